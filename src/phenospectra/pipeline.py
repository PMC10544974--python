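"""Config-driven end-to-end orchestration.

A run reproduces one of two processing eras on synthetic (or user) data:

* ``era_2018`` — single-panel radiometric calibration of the UAS channel
  (85% panel, ratio through the origin), NIR derived from blue and red with
  quantum-efficiency coefficients, handheld platform = broadband radiometer;
* ``era_2020`` — multi-panel empirical-line calibration (five panels,
  2%-85%), native NIR band, handheld platform = full-range hyperspectral
  sensor whose curves are quality-controlled and averaged to broadbands.

Stages run in order ``simulate -> calibrate -> process -> indices -> h2 ->
association``; every stage reads and writes plain files in the run directory
(CSV/JSON/GeoTIFF/GeoJSON), so deleting an intermediate file and re-running
its stage reproduces it exactly, and an identical config and seed give
byte-identical tables. A manifest records the config hash, seed and row
counts per stage.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import synth
from .association import correlation_matrix, linear_regression, pca
from .design import generate_trial_design
from .errors import ValidationError
from .heritability import (
    broad_sense_heritability,
    estimate_variance_components,
)
from .indices import DEFAULT_INDICES, compute_sri_table
from .raster import write_geojson
from .spectral import (
    band_column,
    broadbands_from_curve,
    normalize_by_trial_sd,
    qc_hyperspectral_curve,
)

STAGES = ("simulate", "calibrate", "process", "indices", "h2", "association")

ERA_PRESETS = {
    "era_2018": {
        "uas_panels": "single",
        "derive_nir": True,
        "handheld_platform": synth.RADIOMETER_BROADBAND,
    },
    "era_2020": {
        "uas_panels": "multi",
        "derive_nir": False,
        "handheld_platform": synth.HYPERSPECTRAL,
    },
}

#: UAS bands when NIR is derived rather than measured (no native 800 nm
#: band). The blue and red channels of such cameras owe their NIR
#: reconstruction to strong NIR filter leakage, so they are simulated as
#: spectral mixtures dominated by (blue) or contaminated with (red) the
#: 800 nm response.
UAS_BANDS_NO_NIR = (450.0, 550.0, 680.0, 700.0, 970.0)
UAS_NIR_LEAKAGE_MIXTURES = {
    450.0: ((450.0, 0.05), (800.0, 0.95)),
    680.0: ((680.0, 0.95), (800.0, 0.05)),
}


@dataclass
class RunConfig:
    """Fully determines a pipeline run (era preset + design + seeds)."""

    era: str = "era_2020"
    design: dict = field(
        default_factory=lambda: {
            "kind": "alpha_lattice",
            "n_entries": 60,
            "r": 2,
            "x": 2,
            "block_size": None,
        }
    )
    genetics: dict = field(
        default_factory=lambda: {
            "sigma_G2": 0.16,
            "sigma_GE2": 0.04,
            "sigma_eps2": 0.08,
            "genetic_corr_yield": 0.7,
            "trait_mean": -1.0,
        }
    )
    drift_amplitude: float = 0.05
    drift_spectral_slope: float = 0.05
    handheld_window_hours: float = 6.0   # full window length around solar noon
    uas_window_hours: float = 1.0 / 3.0  # 20-minute capture
    noise_uas_dn: float = 4.0
    noise_handheld: float = 0.004
    indices: tuple = DEFAULT_INDICES
    normalize_handheld: bool = True
    sri_from_normalized: bool = True
    include_orthomosaic: bool = False
    r_convention: str = "design"  # or "one": r=1 when pooling unreplicated trials
    seed: int = 20180801

    def __post_init__(self) -> None:
        if self.era not in ERA_PRESETS:
            raise ValidationError(f"era must be one of {sorted(ERA_PRESETS)}")
        if self.design.get("kind") not in ("alpha_lattice", "augmented_with_checks"):
            raise ValidationError("design.kind must name a supported design")
        if self.handheld_window_hours <= 0 or self.uas_window_hours <= 0:
            raise ValidationError("collection windows must be positive")
        if self.r_convention not in ("design", "one"):
            raise ValidationError("r_convention must be 'design' or 'one'")

    @property
    def preset(self) -> dict:
        return ERA_PRESETS[self.era]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["indices"] = list(self.indices)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config field(s): {sorted(unknown)}")
        if "indices" in doc:
            doc["indices"] = tuple(doc["indices"])
        return cls(**doc)


def _child_seed(seed: int, label: str) -> int:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _uas_sensor(cfg: RunConfig) -> synth.SensorModel:
    derive = cfg.preset["derive_nir"]
    bands = UAS_BANDS_NO_NIR if derive else synth.DEFAULT_BAND_CENTERS
    return synth.uas_sensor(
        band_centers=bands,
        band_mixtures=UAS_NIR_LEAKAGE_MIXTURES if derive else None,
        noise_sd=cfg.noise_uas_dn,
        drift_amplitude=cfg.drift_amplitude,
        drift_spectral_slope=cfg.drift_spectral_slope,
        window_hours=2.0,
    )


def _handheld_sensor(cfg: RunConfig) -> synth.SensorModel:
    kw = dict(
        noise_sd=cfg.noise_handheld,
        drift_amplitude=cfg.drift_amplitude,
        drift_spectral_slope=cfg.drift_spectral_slope,
        window_hours=max(3.0, cfg.handheld_window_hours / 2.0),
    )
    if cfg.preset["handheld_platform"] == synth.HYPERSPECTRAL:
        return synth.hyperspectral_sensor(**kw)
    return synth.radiometer_sensor(**kw)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    d = cfg.design
    design = generate_trial_design(
        d["kind"],
        d["n_entries"],
        n_checks=d.get("n_checks", 0),
        r=d.get("r", 1),
        block_size=d.get("block_size"),
        x=d.get("x", 1),
        check_reps=d.get("check_reps", 3),
        seed=_child_seed(cfg.seed, "design"),
    )
    table, truth = synth.simulate_genetic_values(
        design, seed=_child_seed(cfg.seed, "genetics"), **cfg.genetics
    )

    uas = _uas_sensor(cfg)
    handheld = _handheld_sensor(cfg)
    rng = np.random.default_rng(_child_seed(cfg.seed, "observe"))

    # collection schedule: handheld plots are measured sequentially across
    # the window; the UAS sweeps every plot within its short capture
    hh_off = np.empty(len(table))
    uas_off = np.empty(len(table))
    for _, idx in table.groupby("environment").groups.items():
        k = len(idx)
        hw = cfg.handheld_window_hours / 2.0
        hh_off[table.index.get_indexer(idx)] = np.linspace(-hw, hw, k)
        uw = cfg.uas_window_hours / 2.0
        uas_off[table.index.get_indexer(idx)] = rng.uniform(-uw, uw, k)

    uas_rows, hh_band_rows, hh_curve_rows = [], [], []
    for i, row in enumerate(table.itertuples()):
        spectrum = synth.simulate_canopy_spectrum(row.latent_trait, row.water_proxy)
        ob_u = synth.observe_plot(
            spectrum, uas, uas_off[i], plot_id=row.plot_id, rng=rng
        )
        uas_rows.append(
            {"plot_id": row.plot_id, "time_offset_hours": uas_off[i]}
            | {band_column(c): v for c, v in ob_u.band_values.items()}
        )
        ob_h = synth.observe_plot(
            spectrum, handheld, hh_off[i], plot_id=row.plot_id, rng=rng
        )
        if handheld.platform == synth.HYPERSPECTRAL:
            c = ob_h.curve
            hh_curve_rows.append(
                pd.DataFrame(
                    {
                        "plot_id": row.plot_id,
                        "wavelength": c["wavelength"],
                        "reflectance": c["reflectance"],
                    }
                )
            )
        else:
            hh_band_rows.append(
                {"plot_id": row.plot_id, "time_offset_hours": hh_off[i]}
                | {band_column(c): v for c, v in ob_h.band_values.items()}
            )

    panel_set = (
        synth.single_panel_set()
        if cfg.preset["uas_panels"] == "single"
        else synth.default_panel_set()
    )
    panels = synth.observe_panels(panel_set, uas, time_offset_hours=0.0, rng=rng)

    table.to_csv(out / "plots.csv", index=False)
    pd.DataFrame(uas_rows).to_csv(out / "uas_dn.csv", index=False)
    panels.to_csv(out / "panels_dn.csv", index=False)
    if hh_curve_rows:
        pd.concat(hh_curve_rows, ignore_index=True).to_csv(
            out / "handheld_curves.csv", index=False
        )
    else:
        pd.DataFrame(hh_band_rows).to_csv(out / "handheld_raw.csv", index=False)

    sidecar = {
        "sigma_G2": truth.sigma_G2,
        "sigma_GE2": truth.sigma_GE2,
        "sigma_eps2": truth.sigma_eps2,
        "genetic_corr_yield": truth.genetic_corr_yield,
        "params": truth.params,
        "design": {"x": design.x, "r": design.r, "kind": design.design_kind},
        "seed": cfg.seed,
    }
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)

    if cfg.include_orthomosaic:
        env1 = table[table["environment"] == sorted(table["environment"].unique())[0]]
        bands = synth.DEFAULT_BAND_CENTERS
        vals = {"plot_id": env1["plot_id"].to_numpy()}
        specs = [
            synth.simulate_canopy_spectrum(lt, wp)
            for lt, wp in zip(env1["latent_trait"], env1["water_proxy"])
        ]
        for c in bands:
            vals[band_column(c)] = [
                broadbands_from_curve(s.to_frame(), [c])[c] for s in specs
            ]
        raster, polys = synth.simulate_orthomosaic(
            pd.DataFrame(vals), band_centers=bands,
            seed=_child_seed(cfg.seed, "ortho"),
        )
        raster.to_geotiff(out / "ortho.tif")
        write_geojson(polys, out / "plots.geojson")

    return {"n_plots": len(table), "n_panels": len(panel_set.reflectances)}


def _stage_calibrate(cfg: RunConfig, out: Path) -> dict:
    panels = pd.read_csv(out / "panels_dn.csv")
    method = (
        cal.SINGLE_PANEL if cfg.preset["uas_panels"] == "single" else cal.MULTI_PANEL
    )
    model = cal.fit_empirical_line(panels, method=method)
    model.to_json(out / "calibration.json")

    dn = pd.read_csv(out / "uas_dn.csv")
    result = cal.apply_calibration(dn, model)
    sr = result.values
    derived_floor = 0
    if cfg.preset["derive_nir"]:
        nir = cal.derive_nir(sr["R450"], sr["R680"], normalize=True)
        sr["R800"] = nir.values
        derived_floor = nir.floored_count
    sr.to_csv(out / "uas_sr.csv", index=False)
    return {
        "n_plots": len(sr),
        "clipped": result.clipped_count,
        "nir_floored": derived_floor,
    }


def _stage_process(cfg: RunConfig, out: Path) -> dict:
    centers = synth.DEFAULT_BAND_CENTERS
    qc_dropped = 0
    if (out / "handheld_curves.csv").exists():
        curves = pd.read_csv(out / "handheld_curves.csv")
        rows = []
        for pid, sub in curves.groupby("plot_id", sort=False):
            res = qc_hyperspectral_curve(sub["wavelength"], sub["reflectance"])
            if not res.passed:
                qc_dropped += 1
                continue
            bands = broadbands_from_curve(
                sub.rename(columns={"reflectance": "reflectance"}), centers
            )
            rows.append({"plot_id": pid} | {band_column(c): v for c, v in bands.items()})
        hh = pd.DataFrame(rows)
    else:
        hh = pd.read_csv(out / "handheld_raw.csv").drop(
            columns=["time_offset_hours"], errors="ignore"
        )
    band_cols = [band_column(c) for c in centers]
    hh.to_csv(out / "handheld_sr.csv", index=False)
    if cfg.normalize_handheld:
        plots = pd.read_csv(out / "plots.csv")[["plot_id", "environment"]]
        norm = hh.merge(plots, on="plot_id")
        norm = normalize_by_trial_sd(norm, band_cols, trial_column="environment")
        norm = norm.drop(columns=["environment"])
        norm.to_csv(out / "handheld_sr_normalized.csv", index=False)
    return {"n_plots": len(hh), "qc_dropped": qc_dropped}


def _stage_indices(cfg: RunConfig, out: Path) -> dict:
    plots = pd.read_csv(out / "plots.csv")
    meta = plots[
        ["plot_id", "genotype", "environment", "replicate", "block", "yield_"]
    ]
    logs = {}
    hh_file = (
        "handheld_sr_normalized.csv"
        if cfg.normalize_handheld
        and cfg.sri_from_normalized
        and (out / "handheld_sr_normalized.csv").exists()
        else "handheld_sr.csv"
    )
    for platform, fname in [("uas", "uas_sr.csv"), ("handheld", hh_file)]:
        bands = pd.read_csv(out / fname).drop(
            columns=["time_offset_hours"], errors="ignore"
        )
        table = meta.merge(bands, on="plot_id")
        sri = compute_sri_table(table, indices=cfg.indices)
        sri.to_csv(out / f"sri_{platform}.csv", index=False)
        logs[platform] = len(sri)
    return logs


def _stage_h2(cfg: RunConfig, out: Path) -> dict:
    with open(out / "truth.json", encoding="utf-8") as fh:
        truth = json.load(fh)
    x = truth["design"]["x"]
    r = 1 if cfg.r_convention == "one" else truth["design"]["r"]
    rows = []
    for platform in ("uas", "handheld"):
        sri = pd.read_csv(out / f"sri_{platform}.csv")
        traits = [i for i in cfg.indices if i in sri.columns]
        if platform == "uas":
            traits = ["yield_"] + traits
        for tr in traits:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comp = estimate_variance_components(sri, tr)
            h2 = broad_sense_heritability(comp, x=x, r=r, trait=tr)
            rows.append(
                {
                    "platform": "yield" if tr == "yield_" else platform,
                    "trait": "yield" if tr == "yield_" else tr,
                    "H2": h2.H2,
                    "x": x,
                    "r": r,
                    **{k: v for k, v in comp.as_dict().items() if k != "method"},
                }
            )
    report = pd.DataFrame(rows)
    report.to_csv(out / "h2.csv", index=False)
    return {"n_fits": len(report)}


def _stage_association(cfg: RunConfig, out: Path) -> dict:
    uas = pd.read_csv(out / "sri_uas.csv")
    hh = pd.read_csv(out / "sri_handheld.csv")
    idx_cols = [i for i in cfg.indices if i in uas.columns]
    wide = uas[["plot_id", "environment", "yield_"]].rename(
        columns={"yield_": "grain_yield"}
    )
    for name in idx_cols:
        wide[f"uas_{name}"] = uas[name]
    wide = wide.merge(
        hh[["plot_id"] + [i for i in idx_cols if i in hh.columns]].rename(
            columns={i: f"handheld_{i}" for i in idx_cols}
        ),
        on="plot_id",
        how="left",
    )
    corr = correlation_matrix(wide.drop(columns=["plot_id", "environment"]))
    corr.r.to_csv(out / "correlations.csv")
    corr.n.to_csv(out / "correlations_n.csv")
    corr.to_long().to_csv(out / "correlations_long.csv", index=False)

    reg_rows = []
    for env, sub in wide.groupby("environment"):
        for col in wide.columns:
            if col in ("plot_id", "environment", "grain_yield"):
                continue
            try:
                fit = linear_regression(sub["grain_yield"], sub[col])
            except Exception:
                continue
            reg_rows.append(
                {
                    "environment": env,
                    "predictor": col,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "n": fit.n,
                }
            )
    pd.DataFrame(reg_rows).to_csv(out / "regressions.csv", index=False)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = pca(wide.drop(columns=["plot_id", "environment"]))
    p.loadings.to_csv(out / "pca_loadings.csv")
    p.scores.to_csv(out / "pca_scores.csv")
    with open(out / "pca_variance.json", "w", encoding="utf-8") as fh:
        json.dump(
            {f"Dim{i + 1}": float(v) for i, v in enumerate(p.variance_explained)},
            fh,
            indent=1,
        )
    return {"n_rows": len(wide)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "calibrate": _stage_calibrate,
    "process": _stage_process,
    "indices": _stage_indices,
    "h2": _stage_h2,
    "association": _stage_association,
}


def run_pipeline(config: RunConfig, out_dir, stages=STAGES) -> Path:
    """Execute pipeline stages in order, halting on the first failure.

    Each stage is a pure file contract over the run directory; re-running a
    stage regenerates its outputs exactly. Returns the run directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path, encoding="utf-8") as fh:
            manifest = json.load(fh)
    else:
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stages": {},
        }
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValidationError(f"unknown stage {stage!r}")
        try:
            log = _STAGE_FUNCS[stage](config, out)
        except Exception as exc:
            manifest["failed_stage"] = stage
            with open(manifest_path, "w", encoding="utf-8") as fh:
                json.dump(manifest, fh, indent=1)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = log
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
    return out


# --------------------------------------------------------------------------
# collection-window experiment
# --------------------------------------------------------------------------

def collection_window_experiment(
    n_seeds: int = 20,
    *,
    seed: int = 0,
    n_entries: int = 100,
    r: int = 2,
    x: int = 2,
    handheld_window_hours: float = 6.0,
    uas_window_hours: float = 1.0 / 3.0,
    drift_amplitude: float = 0.05,
    drift_spectral_slope: float = 0.05,
    noise_sd: float = 0.004,
    index: str = "ndvi",
    sigma_G2: float = 0.16,
    sigma_GE2: float = 0.04,
    sigma_eps2: float = 0.08,
    trait_mean: float = -1.0,
) -> pd.DataFrame:
    """Heritability of an index under two collection windows, same genetics.

    For each seed the same trial, genetic values and canopy spectra are
    observed through two otherwise identical reflectance channels that
    differ only in how plot observation times spread around solar noon: a
    handheld-style sequential sweep across ``handheld_window_hours`` and a
    UAS-style capture inside ``uas_window_hours``. Returns one row per seed
    with the REML heritability of the index under each channel.
    """
    from .spectral import narrowband_to_broadband  # local, avoids cycle at import

    registry_bands = {
        "ndvi": (800.0, 680.0),
        "ndre": (800.0, 700.0),
        "nwi": (970.0, 800.0),
    }
    rows = []
    for s in range(n_seeds):
        base = _child_seed(seed, f"window_exp_{s}")
        design = generate_trial_design(
            "alpha_lattice", n_entries, r=r, x=x, seed=base
        )
        table, _ = synth.simulate_genetic_values(
            design,
            sigma_G2=sigma_G2,
            sigma_GE2=sigma_GE2,
            sigma_eps2=sigma_eps2,
            trait_mean=trait_mean,
            seed=base + 1,
        )
        spectra = [
            synth.simulate_canopy_spectrum(lt, wp)
            for lt, wp in zip(table["latent_trait"], table["water_proxy"])
        ]
        rng = np.random.default_rng(base + 2)
        out_row = {"seed": s}
        for label, window in [
            ("handheld", handheld_window_hours),
            ("uas", uas_window_hours),
        ]:
            sensor = synth.radiometer_sensor(
                window_hours=max(window / 2.0, 1e-3),
                drift_amplitude=drift_amplitude,
                drift_spectral_slope=drift_spectral_slope,
                noise_sd=noise_sd,
            )
            offsets = np.empty(len(table))
            for _, idx in table.groupby("environment").groups.items():
                pos = table.index.get_indexer(idx)
                offsets[pos] = np.linspace(-window / 2.0, window / 2.0, len(idx))
            vals = np.empty(len(table))
            for i, spec in enumerate(spectra):
                ob = synth.observe_plot(spec, sensor, offsets[i], rng=rng)
                bands = {c: ob.band_values[c] for c in ob.band_values}
                b1, b2 = registry_bands.get(index, (800.0, 680.0))
                vals[i] = (bands[b1] - bands[b2]) / (bands[b1] + bands[b2])
            fit_table = table[["genotype", "environment", "replicate", "block"]].copy()
            fit_table["value"] = vals
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comp = estimate_variance_components(fit_table, "value")
            h2 = broad_sense_heritability(comp, x=x, r=r)
            out_row[f"h2_{label}"] = h2.H2
        rows.append(out_row)
    return pd.DataFrame(rows)
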