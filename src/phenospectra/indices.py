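"""Spectral reflectance indices.

Five indices computed from broadband surface reflectance at 550, 680, 700,
800 and 970 nm:

====== =========================================================
NDVI   (R800 - R680) / (R800 + R680)
NDRE   (R800 - R700) / (R800 + R700)
TCARI  3 * [(R700 - R680) - 0.2 * (R700 - R550) * (R700 / R680)]
NWI    (R970 - R800) / (R970 + R800)
MTVI   (R700 - R550) / sqrt((2*R800 + 1)^2 - (6*R800 - 5*sqrt(R680)) - 0.5)
====== =========================================================

A lower NWI indicates higher canopy water content. The normalized-difference
indices are invariant to a common positive scaling of all bands; TCARI and
MTVI are not. Undefined values (zero denominators, non-positive radicand)
propagate as NaN with a reason recorded, never as exceptions, so one bad plot
cannot abort a trial-level run.

``VARIANT_REGISTRY`` carries common literature variants of these formulas
(e.g. an 850 nm water index, the MTVI2 numerator); they are disabled unless
requested explicitly by name.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BandMismatchError

log = logging.getLogger(__name__)


def _as_float(*xs):
    return [np.asarray(x, dtype=float) for x in xs]


def _normdiff(a, b):
    a, b = _as_float(a, b)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (a - b) / np.where(denom == 0, 1.0, denom), np.nan)
    return out if out.ndim else float(out)


def ndvi(r800, r680):
    """Normalized Difference Vegetation Index."""
    return _normdiff(r800, r680)


def ndre(r800, r700):
    """Normalized Difference Red Edge index."""
    return _normdiff(r800, r700)


def tcari(r550, r680, r700):
    """Transformed Chlorophyll Absorption Reflectance Index."""
    r550, r680, r700 = _as_float(r550, r680, r700)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(r680 != 0, r700 / np.where(r680 == 0, 1.0, r680), np.nan)
        out = 3.0 * ((r700 - r680) - 0.2 * (r700 - r550) * ratio)
    out = np.where(r680 != 0, out, np.nan)
    return out if out.ndim else float(out)


def nwi(r970, r800):
    """Normalized Water Index; lower values mean higher canopy water content."""
    return _normdiff(r970, r800)


def mtvi(r550, r680, r700, r800):
    """Modified Triangular Vegetation Index."""
    r550, r680, r700, r800 = _as_float(r550, r680, r700, r800)
    with np.errstate(invalid="ignore"):
        root680 = np.sqrt(np.where(r680 >= 0, r680, np.nan))
        radicand = (2.0 * r800 + 1.0) ** 2 - (6.0 * r800 - 5.0 * root680) - 0.5
        out = np.where(
            radicand > 0,
            (r700 - r550) / np.sqrt(np.where(radicand > 0, radicand, 1.0)),
            np.nan,
        )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class IndexSpec:
    name: str
    bands: tuple[int, ...]          # required band centers, nm
    func: callable


INDEX_REGISTRY: dict[str, IndexSpec] = {
    "ndvi": IndexSpec("ndvi", (800, 680), lambda b: ndvi(b[800], b[680])),
    "ndre": IndexSpec("ndre", (800, 700), lambda b: ndre(b[800], b[700])),
    "tcari": IndexSpec("tcari", (550, 680, 700), lambda b: tcari(b[550], b[680], b[700])),
    "nwi": IndexSpec("nwi", (970, 800), lambda b: nwi(b[970], b[800])),
    "mtvi": IndexSpec(
        "mtvi", (550, 680, 700, 800), lambda b: mtvi(b[550], b[680], b[700], b[800])
    ),
}

#: Literature variants; OFF by default, addressable explicitly by name.
VARIANT_REGISTRY: dict[str, IndexSpec] = {
    "nwi_r850": IndexSpec("nwi_r850", (970, 850), lambda b: nwi(b[970], b[850])),
    "mtvi2_numerator": IndexSpec(
        "mtvi2_numerator",
        (550, 680, 700, 800),
        lambda b: 1.5
        * (1.2 * (b[800] - b[550]) - 2.5 * (b[680] - b[550]))
        / np.sqrt((2.0 * b[800] + 1.0) ** 2 - (6.0 * b[800] - 5.0 * np.sqrt(b[680])) - 0.5),
    ),
}

DEFAULT_INDICES = ("ndvi", "ndre", "tcari", "nwi", "mtvi")


def compute_sri_table(
    band_table: pd.DataFrame,
    indices=DEFAULT_INDICES,
    strict: bool = False,
    include_variants: bool = False,
) -> pd.DataFrame:
    """Compute spectral reflectance indices for every plot.

    Parameters
    ----------
    band_table : DataFrame
        One row per plot with band columns named ``R550 ... R970``;
        non-band columns (plot_id, design factors, yield) pass through.
    indices : iterable of str
        Index names from the registry (and the variant registry when
        ``include_variants`` is set).
    strict : bool
        If True a missing band raises :class:`BandMismatchError` naming the
        band and index; otherwise the index is skipped with a logged
        message (recorded in ``result.attrs["skipped"]``).

    Returns
    -------
    DataFrame
        Pass-through columns plus one column per computed index; undefined
        values are NaN and counted in ``result.attrs["undefined"]``.
    """
    registry = dict(INDEX_REGISTRY)
    if include_variants:
        registry.update(VARIANT_REGISTRY)
    out = band_table.copy()
    skipped: dict[str, str] = {}
    undefined: dict[str, int] = {}
    for name in indices:
        if name not in registry:
            raise KeyError(f"unknown index {name!r}")
        spec = registry[name]
        missing = [c for c in spec.bands if f"R{c}" not in band_table.columns]
        if missing:
            msg = f"index {name}: missing band column R{missing[0]}"
            if strict:
                raise BandMismatchError(msg)
            log.info("skipping %s", msg)
            skipped[name] = f"R{missing[0]}"
            continue
        bands = {c: band_table[f"R{c}"].to_numpy(dtype=float) for c in spec.bands}
        vals = spec.func(bands)
        out[name] = vals
        undefined[name] = int(np.sum(~np.isfinite(np.atleast_1d(vals))))
    out.attrs["skipped"] = skipped
    out.attrs["undefined"] = undefined
    return out
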