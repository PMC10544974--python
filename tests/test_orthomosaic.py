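"""Orthomosaic rendering, raster I/O, soil masking, zonal extraction."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

import phenospectra as ps
from phenospectra.errors import ExtractionError, LayoutError
from phenospectra.raster import Raster
from phenospectra.spectral import band_column


def _plot_values(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "plot_id": [f"p{i:03d}" for i in range(n)],
            "R680": rng.uniform(0.05, 0.15, n),
            "R800": rng.uniform(0.35, 0.55, n),
        }
    )


class TestSimulateOrthomosaic:
    def test_noiseless_zonal_means_equal_plot_values(self):
        vals = _plot_values(12)
        raster, polys = ps.simulate_orthomosaic(vals, noise_sd=0.0)
        out = ps.extract_plot_means(raster, polys)
        merged = vals.merge(out, on="plot_id", suffixes=("", "_got"))
        np.testing.assert_allclose(merged["R680_got"], merged["R680"], atol=1e-12)
        np.testing.assert_allclose(merged["R800_got"], merged["R800"], atol=1e-12)

    def test_polygon_count_matches_plot_count(self):
        raster, polys = ps.simulate_orthomosaic(_plot_values(195))
        assert len(polys) == 195

    def test_soil_background_is_below_vegetation_threshold(self):
        vals = _plot_values(4)
        raster, polys = ps.simulate_orthomosaic(vals, inset=0.2)
        res = ps.mask_soil(raster, threshold=0.3)
        # every pixel outside the sown footprints (polygons grown back by the
        # 0.2 m inset) is soil: below threshold and masked
        in_any = np.zeros(raster.shape, dtype=bool)
        from phenospectra.spectral import _pixels_inside

        for _, geom in polys:
            in_any |= _pixels_inside(raster, geom.buffer(0.2, join_style="mitre"))
        assert res.index_map[~in_any].max() < 0.3
        assert res.mask[~in_any].all()

    def test_pure_soil_raster_fully_masked(self):
        vals = _plot_values(4)
        raster, _ = ps.simulate_orthomosaic(vals)
        soil_only = raster.copy()
        from phenospectra.synth import soil_reflectance_at

        for i, c in enumerate(soil_only.band_centers):
            soil_only.data[i].fill(soil_reflectance_at(np.array([c]))[0])
        res = ps.mask_soil(soil_only, threshold=0.3)
        assert res.mask.all()

    def test_coarse_gsd_rejected(self):
        with pytest.raises(LayoutError):
            ps.simulate_orthomosaic(_plot_values(4), gsd=0.5)

    def test_overlapping_footprints_rejected(self):
        vals = _plot_values(2)
        with pytest.raises(LayoutError):
            ps.simulate_orthomosaic(
                vals, positions={"p000": (2.0, 2.0), "p001": (2.5, 2.5)}
            )

    def test_deterministic_under_seed(self):
        vals = _plot_values(4)
        r1, _ = ps.simulate_orthomosaic(vals, noise_sd=0.01, seed=5)
        r2, _ = ps.simulate_orthomosaic(vals, noise_sd=0.01, seed=5)
        assert np.array_equal(r1.data, r2.data)


class TestRasterIO:
    def test_geotiff_roundtrip(self, tmp_path):
        raster, _ = ps.simulate_orthomosaic(_plot_values(4))
        path = tmp_path / "ortho.tif"
        raster.to_geotiff(path)
        back = Raster.from_geotiff(path)
        assert back.band_centers == raster.band_centers
        assert back.pixel_size == pytest.approx(raster.pixel_size)
        assert back.x_origin == pytest.approx(raster.x_origin)
        assert back.y_origin == pytest.approx(raster.y_origin)
        np.testing.assert_allclose(back.data, raster.data, atol=1e-6)

    def test_geojson_roundtrip(self, tmp_path):
        _, polys = ps.simulate_orthomosaic(_plot_values(3))
        path = tmp_path / "plots.geojson"
        ps.write_geojson(polys, path)
        back = ps.read_geojson(path)
        assert [pid for pid, _ in back] == [pid for pid, _ in polys]
        for (_, g1), (_, g2) in zip(back, polys):
            assert g1.equals(g2)


class TestSoilMasking:
    def _half_soil_fixture(self):
        """One plot whose left half is soil pixels, right half canopy."""
        canopy = {"R680": 0.08, "R800": 0.5}
        soil = {"R680": 0.20, "R800": 0.23}
        data = np.empty((2, 10, 10))
        for i, b in enumerate(("R680", "R800")):
            data[i, :, :5] = soil[b]
            data[i, :, 5:] = canopy[b]
        raster = Raster(data, (680.0, 800.0), x_origin=0, y_origin=1.0, pixel_size=0.1)
        poly = box(0.05, 0.05, 0.95, 0.95)
        return raster, [("plot", poly)], canopy, soil

    def test_masked_mean_recovers_canopy_not_blend(self):
        raster, polys, canopy, soil = self._half_soil_fixture()
        res = ps.mask_soil(raster, threshold=0.3, polygons=polys)
        out = ps.extract_plot_means(raster, polys, mask=res.mask)
        assert out.loc[0, "R800"] == pytest.approx(canopy["R800"])
        assert out.loc[0, "R680"] == pytest.approx(canopy["R680"])
        blend = 0.5 * (canopy["R800"] + soil["R800"])
        assert abs(out.loc[0, "R800"] - blend) > 0.1
        assert res.masked_fraction.loc[0, "masked_fraction"] == pytest.approx(
            0.5, abs=0.1
        )

    def test_pure_canopy_plot_unmasked(self):
        data = np.stack([np.full((5, 5), 0.08), np.full((5, 5), 0.7)])
        raster = Raster(data, (680.0, 800.0), 0, 0.5, 0.1)
        res = ps.mask_soil(raster)
        assert not res.mask.any()

    def test_all_masked_plot_flagged_missing(self):
        data = np.stack([np.full((5, 5), 0.20), np.full((5, 5), 0.23)])
        raster = Raster(data, (680.0, 800.0), 0, 0.5, 0.1)
        res = ps.mask_soil(raster)
        with pytest.warns(UserWarning, match="all pixels masked"):
            out = ps.extract_plot_means(
                raster, [("p", box(0.1, 0.1, 0.4, 0.4))], mask=res.mask
            )
        assert out.loc[0, "all_masked"]
        assert np.isnan(out.loc[0, "R800"])


class TestExtractPlotMeans:
    def test_constant_band_returns_constant(self):
        data = np.full((1, 8, 8), 0.42)
        raster = Raster(data, (800.0,), 0, 0.8, 0.1)
        out = ps.extract_plot_means(raster, [("p", box(0.1, 0.1, 0.6, 0.6))])
        assert out.loc[0, "R800"] == pytest.approx(0.42)

    def test_checkerboard_matches_pixel_center_enumeration(self):
        rows = cols = 6
        data = np.indices((rows, cols)).sum(axis=0) % 2
        raster = Raster(data[None].astype(float), (800.0,), 0, 0.6, 0.1)
        poly = box(0.12, 0.17, 0.43, 0.52)
        # brute-force oracle over pixel centers
        total, n = 0.0, 0
        for i in range(rows):
            for j in range(cols):
                x = (j + 0.5) * 0.1
                y = 0.6 - (i + 0.5) * 0.1
                if shapely.contains_xy(poly, x, y):
                    total += data[i, j]
                    n += 1
        out = ps.extract_plot_means(raster, [("p", poly)])
        assert out.loc[0, "n_pixels"] == n
        assert out.loc[0, "R800"] == pytest.approx(total / n)

    def test_polygon_outside_raster_names_plot(self):
        raster = Raster(np.zeros((1, 4, 4)), (800.0,), 0, 0.4, 0.1)
        with pytest.raises(ExtractionError, match="far_plot"):
            ps.extract_plot_means(raster, [("far_plot", box(10, 10, 11, 11))])
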