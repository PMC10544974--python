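"""Spectral observation handling.

Covers the ground-platform processing chain — quality control of hyperspectral
reflectance curves, synthesis of broadband values by averaging narrowbands
inside a window, within-trial standard-deviation normalization — and the
raster chain: NDVI-threshold soil masking and zonal plot-mean extraction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .errors import (
    CoverageError,
    DegenerateGroupError,
    ExtractionError,
)
from .raster import Raster


def band_column(center: float) -> str:
    """Canonical column name for a broadband center, e.g. ``R800``."""
    return f"R{int(round(center))}"


@dataclass
class SpectralObservation:
    """One plot observation from a single platform.

    Exactly one of ``band_values`` (broadband platforms) or ``curve``
    (hyperspectral platform, a DataFrame with columns ``wavelength`` and
    ``reflectance``) is set. ``is_dn`` marks raw digital numbers still
    requiring radiometric calibration (UAS broadband channel).
    """

    plot_id: str
    platform: str
    band_values: dict[float, float] | None = None
    curve: pd.DataFrame | None = None
    timestamp_offset_hours: float = 0.0
    qc_flag: str = "ok"
    is_dn: bool = False

    def __post_init__(self) -> None:
        if (self.band_values is None) == (self.curve is None):
            raise ValueError("exactly one of band_values or curve must be set")
        if self.curve is not None:
            wl = np.asarray(self.curve["wavelength"])
            if not np.all(np.diff(wl) > 0):
                raise ValueError("curve wavelengths must be strictly increasing")


@dataclass
class QCResult:
    passed: bool
    reason: str | None = None


@dataclass
class QCRules:
    """Switchable criteria for flagging abnormal curves below 1000 nm.

    Defaults: reflectance below -0.01 or above 1.2, a red-edge inversion
    (mean reflectance on [760, 800] nm lower than on [660, 690] nm), or a
    jump larger than 0.3 between adjacent samples.
    """

    min_reflectance: float | None = -0.01
    max_reflectance: float | None = 1.2
    red_edge_inversion: bool = True
    spike_threshold: float | None = 0.3
    upper_limit_nm: float = 1000.0


DEFAULT_QC = QCRules()


def qc_hyperspectral_curve(
    wavelengths, reflectance, rules: QCRules = DEFAULT_QC
) -> QCResult:
    """Screen a reflectance curve for abnormal shape below 1000 nm.

    Raises
    ------
    CoverageError
        If the curve does not cover [400, 1000] nm.
    """
    wl = np.asarray(wavelengths, dtype=float)
    r = np.asarray(reflectance, dtype=float)
    if wl[0] > 400.0 or wl[-1] < rules.upper_limit_nm:
        raise CoverageError(
            f"curve covers [{wl[0]:.0f}, {wl[-1]:.0f}] nm; QC needs [400, 1000]"
        )
    sub = wl < rules.upper_limit_nm
    rs = r[sub]
    if rules.min_reflectance is not None and np.any(rs < rules.min_reflectance):
        return QCResult(False, "negative_reflectance")
    if rules.max_reflectance is not None and np.any(rs > rules.max_reflectance):
        return QCResult(False, "reflectance_above_ceiling")
    if rules.red_edge_inversion:
        nir = rs[(wl[sub] >= 760) & (wl[sub] <= 800)]
        red = rs[(wl[sub] >= 660) & (wl[sub] <= 690)]
        if len(nir) and len(red) and nir.mean() < red.mean():
            return QCResult(False, "red_edge_inversion")
    if rules.spike_threshold is not None:
        if np.any(np.abs(np.diff(rs)) > rules.spike_threshold):
            return QCResult(False, "spike")
    return QCResult(True)


def narrowband_to_broadband(
    wavelengths, reflectance, center: float, width: float = 50.0
) -> float:
    """Average narrowband samples inside a broadband window.

    The window is left-closed, right-open: ``[center - width/2,
    center + width/2)``.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    wl = np.asarray(wavelengths, dtype=float)
    r = np.asarray(reflectance, dtype=float)
    lo, hi = center - width / 2.0, center + width / 2.0
    inside = (wl >= lo) & (wl < hi)
    if not inside.any():
        raise CoverageError(f"no samples in window [{lo}, {hi}) nm")
    return float(r[inside].mean())


def broadbands_from_curve(
    curve: pd.DataFrame, centers, width: float = 50.0
) -> dict[float, float]:
    """Synthesize a set of broadbands from one hyperspectral curve."""
    wl = curve["wavelength"].to_numpy()
    r = curve["reflectance"].to_numpy()
    return {
        float(c): narrowband_to_broadband(wl, r, c, width) for c in centers
    }


def normalize_by_trial_sd(
    table: pd.DataFrame,
    value_columns,
    trial_column: str = "environment",
) -> pd.DataFrame:
    """Divide each value by the sample SD (ddof=1) of its trial-band group.

    Returns a copy of ``table`` with the value columns replaced by the
    normalized values. Each group must have at least two plots and nonzero
    spread.

    Raises
    ------
    DegenerateGroupError
        Naming the (trial, band) group whose SD is zero or undefined.
    """
    out = table.copy()
    for trial, idx in table.groupby(trial_column).groups.items():
        for col in value_columns:
            vals = table.loc[idx, col].astype(float)
            if len(vals) < 2:
                raise DegenerateGroupError(
                    f"trial {trial!r}, band {col!r}: fewer than 2 plots"
                )
            sd = vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise DegenerateGroupError(
                    f"trial {trial!r}, band {col!r}: zero standard deviation"
                )
            out.loc[idx, col] = vals / sd
    return out


@dataclass
class SoilMaskResult:
    raster: Raster          # masked copy; soil pixels are NaN
    mask: np.ndarray        # True where pixels were masked out
    index_map: np.ndarray
    masked_fraction: pd.DataFrame | None = None


def mask_soil(
    raster: Raster,
    threshold: float = 0.3,
    red_center: float = 680.0,
    nir_center: float = 800.0,
    polygons=None,
) -> SoilMaskResult:
    """Mask soil/background pixels by thresholding NDVI.

    Pixels with ``NDVI < threshold`` are set to NaN in every band. When plot
    ``polygons`` are given, the per-plot masked fraction is reported.
    """
    red = raster.band(red_center)
    nir = raster.band(nir_center)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = (nir - red) / (nir + red)
    mask = ~(ndvi >= threshold)  # NaN NDVI is masked too
    out = raster.copy()
    out.data[:, mask] = np.nan
    frac = None
    if polygons is not None:
        rows = []
        for pid, geom in polygons:
            inside = _pixels_inside(raster, geom)
            n = int(inside.sum())
            rows.append(
                {
                    "plot_id": pid,
                    "n_pixels": n,
                    "masked_fraction": float(mask[inside].mean()) if n else np.nan,
                }
            )
        frac = pd.DataFrame(rows)
    return SoilMaskResult(out, mask, ndvi, frac)


def _pixels_inside(raster: Raster, geom) -> np.ndarray:
    """Boolean grid of pixels whose *centers* fall inside the geometry."""
    X, Y = raster.pixel_centers()
    xmin, ymin, xmax, ymax = geom.bounds
    candidate = (X >= xmin) & (X <= xmax) & (Y >= ymin) & (Y <= ymax)
    inside = np.zeros(raster.shape, dtype=bool)
    if candidate.any():
        idx = np.nonzero(candidate)
        inside[idx] = shapely.contains_xy(geom, X[idx], Y[idx])
    return inside


def extract_plot_means(
    raster: Raster,
    polygons,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Zonal means per plot polygon, pixel-center-in-polygon rule.

    Parameters
    ----------
    raster : Raster
    polygons : iterable of (plot_id, shapely geometry)
    mask : 2-D bool array, optional
        Pixels to exclude (True = excluded), e.g. a soil mask. NaN pixels in
        the raster are always excluded.

    Returns
    -------
    pandas.DataFrame
        Columns ``plot_id``, one ``R<center>`` column per band,
        ``n_pixels``, ``masked_fraction``, ``all_masked``. A plot whose
        pixels are all masked gets NaN means and ``all_masked=True``.

    Raises
    ------
    ExtractionError
        If a polygon contains no pixel center of the raster (carries the
        plot_id).
    """
    xmin_r, ymin_r, xmax_r, ymax_r = raster.bounds
    rows = []
    for pid, geom in polygons:
        gxmin, gymin, gxmax, gymax = geom.bounds
        if gxmax < xmin_r or gxmin > xmax_r or gymax < ymin_r or gymin > ymax_r:
            raise ExtractionError(f"plot {pid!r}: polygon outside raster extent")
        inside = _pixels_inside(raster, geom)
        if not inside.any():
            raise ExtractionError(f"plot {pid!r}: no pixel centers in polygon")
        usable = inside.copy()
        if mask is not None:
            usable &= ~mask
        usable &= np.isfinite(raster.data).all(axis=0)
        n_in = int(inside.sum())
        n_use = int(usable.sum())
        row = {"plot_id": pid}
        for i, c in enumerate(raster.band_centers):
            row[band_column(c)] = (
                float(raster.data[i][usable].mean()) if n_use else np.nan
            )
        row["n_pixels"] = n_in
        row["masked_fraction"] = 1.0 - n_use / n_in
        row["all_masked"] = n_use == 0
        if n_use == 0:
            warnings.warn(f"plot {pid!r}: all pixels masked; mean set missing")
        rows.append(row)
    return pd.DataFrame(rows)
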