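"""Empirical-line radiometric calibration and NIR band derivation.

Raw digital numbers (DN) from a broadband camera are mapped to surface
reflectance (SR) with a per-band linear relation ``SR = DN * m + b`` fitted
against calibration panels of known reflectance:

* **multi-panel** — ordinary least squares of true panel reflectance on
  observed panel DN (at least two distinct panels); slope and intercept both
  free, so any affine sensor transfer is inverted exactly in the noiseless
  limit.
* **single-panel** — a ratio through the origin, ``m = SR_panel / DN_panel``,
  ``b = 0``. A sensor offset therefore survives calibration as a
  reflectance-dependent bias, the data-quality weakness of the one-panel
  strategy.

Cameras lacking a native NIR band derive it from calibrated blue and red
reflectance with quantum-efficiency coefficients,
``NIR = 2.921 * Blue - 0.754 * Red``, optionally normalized by 3.07 when
indices are computed from that channel.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BandMismatchError, CalibrationError

SINGLE_PANEL = "single_panel"
MULTI_PANEL = "multi_panel"

#: Reflectance ceiling applied after calibration; above 1.0 to tolerate
#: specular returns, but counted and reported.
CLIP_CEILING = 1.2


@dataclass(frozen=True)
class QuantumEfficiencyCoefficients:
    """Coefficients of the NIR derivation ``c_blue*Blue - c_red*Red``."""

    c_blue: float = 2.921
    c_red: float = 0.754
    nir_norm: float = 3.07

    def __post_init__(self) -> None:
        if self.nir_norm <= 0:
            raise CalibrationError("nir_norm must be > 0")


@dataclass
class BandCalibration:
    m: float
    b: float
    r_squared: float
    n_panels: int
    flagged: bool = False  # negative fitted slope


@dataclass
class CalibrationModel:
    """Per-band empirical-line coefficients."""

    method: str
    bands: dict[str, BandCalibration] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in (SINGLE_PANEL, MULTI_PANEL):
            raise CalibrationError(f"unknown calibration method {self.method!r}")

    def to_json(self, path=None) -> str:
        doc = {
            "method": self.method,
            "bands": {
                k: {
                    "m": v.m,
                    "b": v.b,
                    "r_squared": v.r_squared,
                    "n_panels": v.n_panels,
                    "flagged": v.flagged,
                }
                for k, v in self.bands.items()
            },
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationModel":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            try:
                doc = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source, encoding="utf-8") as fh:
                    doc = json.load(fh)
        bands = {k: BandCalibration(**v) for k, v in doc["bands"].items()}
        return cls(method=doc["method"], bands=bands)


def fit_empirical_line(
    panel_dn: pd.DataFrame,
    panel_truth: pd.DataFrame | None = None,
    method: str = MULTI_PANEL,
) -> CalibrationModel:
    """Fit per-band empirical-line coefficients from panel readings.

    Parameters
    ----------
    panel_dn : DataFrame
        Long table with columns ``panel_id``, ``band``, ``dn`` and, if
        ``panel_truth`` is not given separately, ``true_reflectance``.
    panel_truth : DataFrame, optional
        ``panel_id``, ``band``, ``true_reflectance`` rows to merge on.
    method : str
        ``"multi_panel"`` (OLS, >= 2 distinct panels) or ``"single_panel"``
        (ratio through the origin, exactly 1 panel).

    Raises
    ------
    CalibrationError
        On a panel-count mismatch with the method, or identical DN across
        panels (degenerate fit). A negative fitted slope does not raise; the
        band is returned flagged and a warning is emitted.
    """
    table = panel_dn
    if panel_truth is not None:
        table = panel_dn.merge(panel_truth, on=["panel_id", "band"])
    if "true_reflectance" not in table.columns:
        raise CalibrationError("panel table lacks true_reflectance")

    model = CalibrationModel(method=method)
    for band, grp in table.groupby("band"):
        dn = grp["dn"].to_numpy(dtype=float)
        sr = grp["true_reflectance"].to_numpy(dtype=float)
        n = grp["panel_id"].nunique()
        if method == SINGLE_PANEL:
            if n != 1:
                raise CalibrationError(
                    f"band {band}: single-panel calibration needs exactly 1 panel, got {n}"
                )
            if np.any(dn == 0):
                raise CalibrationError(f"band {band}: zero DN on the panel")
            m = float(np.mean(sr / dn))
            entry = BandCalibration(m=m, b=0.0, r_squared=1.0, n_panels=1)
        else:
            if n < 2:
                raise CalibrationError(
                    f"band {band}: multi-panel calibration needs >= 2 panels, got {n}"
                )
            if np.ptp(dn) == 0:
                raise CalibrationError(
                    f"band {band}: identical DN across panels (degenerate fit)"
                )
            m, b = np.polyfit(dn, sr, 1)
            pred = m * dn + b
            ss_tot = float(np.sum((sr - sr.mean()) ** 2))
            ss_res = float(np.sum((sr - pred) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            entry = BandCalibration(
                m=float(m), b=float(b), r_squared=r2, n_panels=int(n)
            )
        if entry.m <= 0:
            entry.flagged = True
            warnings.warn(f"band {band}: non-positive fitted slope {entry.m:.4g}")
        model.bands[str(band)] = entry
    return model


@dataclass
class CalibratedValues:
    values: pd.DataFrame | np.ndarray
    clipped_count: int


def apply_calibration(dn_values, model: CalibrationModel) -> CalibratedValues:
    """Apply ``SR = DN * m + b`` elementwise; clip SR to [0, 1.2].

    ``dn_values`` may be a DataFrame whose band columns match the model's
    band names (other columns pass through untouched), or a mapping
    ``band -> array``. The number of clipped values is reported.

    Raises
    ------
    BandMismatchError
        If a band present in the input has no calibration entry.
    """
    if isinstance(dn_values, pd.DataFrame):
        out = dn_values.copy()
        clipped = 0
        band_cols = [c for c in out.columns if c in model.bands or c.startswith("R")]
        for col in band_cols:
            if col not in model.bands:
                raise BandMismatchError(f"no calibration for band {col!r}")
            cal = model.bands[col]
            sr = out[col].to_numpy(dtype=float) * cal.m + cal.b
            clipped += int(np.sum((sr < 0) | (sr > CLIP_CEILING)))
            out[col] = np.clip(sr, 0.0, CLIP_CEILING)
        return CalibratedValues(out, clipped)
    if isinstance(dn_values, dict):
        out_d = {}
        clipped = 0
        for band, arr in dn_values.items():
            key = str(band)
            if key not in model.bands:
                raise BandMismatchError(f"no calibration for band {key!r}")
            cal = model.bands[key]
            sr = np.asarray(arr, dtype=float) * cal.m + cal.b
            clipped += int(np.sum((sr < 0) | (sr > CLIP_CEILING)))
            out_d[band] = np.clip(sr, 0.0, CLIP_CEILING)
        return CalibratedValues(out_d, clipped)
    raise TypeError("dn_values must be a DataFrame or a mapping band -> values")


@dataclass
class DerivedNIR:
    values: np.ndarray
    floored_count: int


def derive_nir(
    blue_sr,
    red_sr,
    coeffs: QuantumEfficiencyCoefficients = QuantumEfficiencyCoefficients(),
    normalize: bool = False,
) -> DerivedNIR:
    """Derive NIR reflectance from calibrated blue and red bands.

    ``NIR_raw = c_blue * Blue - c_red * Red``; negative values are floored
    at 0 with a warning count. With ``normalize=True`` the result is divided
    by ``nir_norm`` (applied when spectral indices are computed from a
    channel whose NIR is derived rather than measured).
    """
    blue = np.asarray(blue_sr, dtype=float)
    red = np.asarray(red_sr, dtype=float)
    raw = coeffs.c_blue * blue - coeffs.c_red * red
    floored = int(np.sum(raw < 0))
    if floored:
        warnings.warn(f"{floored} derived NIR value(s) below 0 floored")
    out = np.maximum(raw, 0.0)
    if normalize:
        out = out / coeffs.nir_norm
    return DerivedNIR(out, floored)
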