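"""Synthetic field-trial generator.

Emulates the data-collection contrast between a fast-flying UAS multispectral
camera and slower handheld radiometers over the same genetic material:

* latent genetic values for a canopy trait and grain yield, decomposed into
  genotype, genotype-by-environment, design (replicate/block) and residual
  effects with configurable variances;
* a parametric vegetation reflectance curve (338-2515 nm) driven by the latent
  canopy trait (chlorophyll/cover) and a water-status proxy;
* three observation channels — UAS broadband digital numbers plus
  calibration-panel readings, handheld broadband radiometer reflectances, and
  handheld hyperspectral curves — each subject to a multiplicative solar-drift
  process that grows linearly with time from solar noon;
* a georeferenced multi-band orthomosaic with per-plot polygons and a flat,
  low-NDVI soil background.

Illumination error has a deterministic and a stochastic part, both exactly 1
at solar noon. The deterministic drift multiplier at ``t`` hours from noon
factorizes into an intensity part ``1 - a * |t|``, common to all wavelengths
(it cancels in band-ratio indices), and a spectral-slope part
``1 + s * |t| * clip((lambda - 800) / 400, -1, 1)`` that tilts the measured
spectrum as incident light reddens with growing air mass. The stochastic
part models cloud haze and solar change accrued since the last white-panel
calibration as a random walk: each observation carries a multiplicative
intensity error, a spectral-tilt error, and a smooth chromatic error
(correlation length ~120 nm, so red and near-infrared calibration errors
drift partly independently), all with standard deviation growing as
``sqrt(|t|)``. The chromatic component is what degrades ratio indices such
as NDVI when collection stretches over hours.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.strtree import STRtree

from .design import TrialDesign
from .errors import LayoutError, ParameterError, SchedulingError
from .raster import Raster
from .spectral import SpectralObservation, band_column, narrowband_to_broadband

UAS_BROADBAND = "uas_broadband"
RADIOMETER_BROADBAND = "radiometer_broadband"
HYPERSPECTRAL = "hyperspectral"

#: Broadband centers (nm) shared by the UAS camera and the radiometer presets;
#: the five index bands plus blue (used for NIR derivation).
DEFAULT_BAND_CENTERS = (450.0, 550.0, 680.0, 700.0, 800.0, 970.0)


# --------------------------------------------------------------------------
# genetics
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Simulation truth sidecar: variance targets and realized effects."""

    sigma_G2: float
    sigma_GE2: float
    sigma_eps2: float
    genetic_corr_yield: float
    genotype_effects: pd.DataFrame   # genotype, trait_effect, yield_effect
    ge_effects: pd.DataFrame         # genotype, environment, trait/yield effects
    plot_errors: pd.DataFrame        # plot_id, trait_error, yield_error
    params: dict = field(default_factory=dict)


def simulate_genetic_values(
    design: TrialDesign,
    *,
    sigma_G2: float = 1.0,
    sigma_GE2: float = 0.25,
    sigma_eps2: float = 0.5,
    sigma_rep2: float = 0.0,
    sigma_block2: float = 0.0,
    genetic_corr_yield: float = 0.7,
    trait_mean: float = 0.0,
    yield_mean: float = 6.0,
    water_coupling: float = 0.8,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw latent genetic values and grain yield for every plot.

    The canopy trait of plot *ijkl* is ``mu + G_i + GE_ij + rep_jk +
    block_jkl + eps``; grain yield follows the same decomposition with its
    own draws, sharing genotype effects with the canopy trait through
    ``genetic_corr_yield``. All effects are Gaussian with the stated
    variances. ``water_proxy`` (in (0, 1)) is positively coupled to the
    yield genotype effect, so canopy water content rises with genetic yield
    potential.

    Returns
    -------
    (plot_table, truth)
        ``plot_table`` is the design's plot frame plus ``latent_trait``,
        ``water_proxy`` and ``yield_`` columns; ``truth`` records the
        realized effects and all parameters.
    """
    for name, v in [
        ("sigma_G2", sigma_G2),
        ("sigma_GE2", sigma_GE2),
        ("sigma_eps2", sigma_eps2),
        ("sigma_rep2", sigma_rep2),
        ("sigma_block2", sigma_block2),
    ]:
        if v < 0:
            raise ParameterError(f"{name} must be >= 0, got {v}")
    if abs(genetic_corr_yield) > 1:
        raise ParameterError("|genetic_corr_yield| must be <= 1")

    rng = np.random.default_rng(seed)
    plots = design.plots
    genos = sorted(plots["genotype"].unique())
    envs = sorted(plots["environment"].unique())
    rho = genetic_corr_yield

    g_trait = rng.normal(0.0, np.sqrt(sigma_G2), len(genos))
    g_indep = rng.normal(0.0, np.sqrt(sigma_G2), len(genos))
    if sigma_G2 > 0:
        g_yield = rho * g_trait + np.sqrt(1.0 - rho**2) * g_indep
    else:
        g_yield = np.zeros(len(genos))
    gmap_t = dict(zip(genos, g_trait))
    gmap_y = dict(zip(genos, g_yield))

    ge_index = pd.MultiIndex.from_product([genos, envs], names=["genotype", "environment"])
    ge_t = rng.normal(0.0, np.sqrt(sigma_GE2), len(ge_index))
    ge_y = rng.normal(0.0, np.sqrt(sigma_GE2), len(ge_index))
    ge_map_t = dict(zip(ge_index, ge_t))
    ge_map_y = dict(zip(ge_index, ge_y))

    def _design_effects(col, sigma2):
        levels = sorted((plots["environment"] + ":" + plots[col]).unique())
        draws = rng.normal(0.0, np.sqrt(sigma2), len(levels))
        return dict(zip(levels, draws))

    rep_t = _design_effects("replicate", sigma_rep2)
    rep_y = _design_effects("replicate", sigma_rep2)
    blk_t = _design_effects("block", sigma_block2)
    blk_y = _design_effects("block", sigma_block2)

    eps_t = rng.normal(0.0, np.sqrt(sigma_eps2), len(plots))
    eps_y = rng.normal(0.0, np.sqrt(sigma_eps2), len(plots))

    rep_key = plots["environment"] + ":" + plots["replicate"]
    blk_key = plots["environment"] + ":" + plots["block"]
    ge_key = list(zip(plots["genotype"], plots["environment"]))

    latent = (
        trait_mean
        + plots["genotype"].map(gmap_t).to_numpy()
        + np.array([ge_map_t[k] for k in ge_key])
        + rep_key.map(rep_t).to_numpy()
        + blk_key.map(blk_t).to_numpy()
        + eps_t
    )
    yld = (
        yield_mean
        + plots["genotype"].map(gmap_y).to_numpy()
        + np.array([ge_map_y[k] for k in ge_key])
        + rep_key.map(rep_y).to_numpy()
        + blk_key.map(blk_y).to_numpy()
        + eps_y
    )

    # water status follows genetic yield potential, with independent noise
    gy_plot = plots["genotype"].map(gmap_y).to_numpy()
    scale = np.sqrt(sigma_G2) if sigma_G2 > 0 else 1.0
    w_lin = water_coupling * gy_plot / scale + np.sqrt(
        max(0.0, 1.0 - water_coupling**2)
    ) * rng.normal(0.0, 1.0, len(plots))
    water = 1.0 / (1.0 + np.exp(-w_lin))

    table = plots.copy()
    table["latent_trait"] = latent
    table["water_proxy"] = water
    table["yield_"] = yld

    truth = GroundTruth(
        sigma_G2=sigma_G2,
        sigma_GE2=sigma_GE2,
        sigma_eps2=sigma_eps2,
        genetic_corr_yield=rho,
        genotype_effects=pd.DataFrame(
            {"genotype": genos, "trait_effect": g_trait, "yield_effect": g_yield}
        ),
        ge_effects=pd.DataFrame(
            {
                "genotype": ge_index.get_level_values(0),
                "environment": ge_index.get_level_values(1),
                "trait_effect": ge_t,
                "yield_effect": ge_y,
            }
        ),
        plot_errors=pd.DataFrame(
            {"plot_id": plots["plot_id"], "trait_error": eps_t, "yield_error": eps_y}
        ),
        params={
            "sigma_rep2": sigma_rep2,
            "sigma_block2": sigma_block2,
            "trait_mean": trait_mean,
            "yield_mean": yield_mean,
            "water_coupling": water_coupling,
            "seed": seed,
        },
    )
    return table, truth


# --------------------------------------------------------------------------
# canopy spectra
# --------------------------------------------------------------------------

@dataclass
class CanopySpectrum:
    """Full-range reflectance curve with its latent drivers."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    chlorophyll_proxy: float
    water_proxy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength": self.wavelengths, "reflectance": self.reflectance}
        )


#: Canopy-fraction link: fraction = sigmoid((latent - midpoint) / scale).
CANOPY_MIDPOINT = -2.0
CANOPY_SCALE = 0.8

_WL_DEFAULT = np.linspace(338.0, 2515.0, 727)  # ~3 nm steps, SVC full range


def soil_reflectance_at(wavelengths) -> np.ndarray:
    """Flat, gently sloped soil spectrum (reflectance ~0.13-0.28, NDVI ~0.07)."""
    wl = np.asarray(wavelengths, dtype=float)
    return np.clip(0.13 + 0.15 * (wl - 400.0) / 600.0, 0.13, 0.28)


def simulate_canopy_spectrum(
    latent_trait: float,
    water_proxy: float = 0.5,
    wavelengths: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CanopySpectrum:
    """Parametric vegetation reflectance curve.

    A soil endmember and a vegetation endmember are mixed by a canopy
    fraction that increases logistically with ``latent_trait``. The
    vegetation endmember has a chlorophyll green peak at 550 nm, deep red
    absorption at 680 nm, a logistic red edge rising to a near-infrared
    plateau, and water-absorption dips (970, 1200, 1450, 1940 nm) whose
    depth scales with ``water_proxy``; higher water status lowers 970 nm
    reflectance. Higher ``latent_trait`` deepens the 680 nm absorption and
    raises the 800 nm plateau, so NDVI is strictly increasing in the latent
    trait. Reflectance is clamped to [0, 1.2].
    """
    wl = _WL_DEFAULT if wavelengths is None else np.asarray(wavelengths, float)
    if wl[0] > 338.0 or wl[-1] < 2515.0 or np.max(np.diff(wl)) > 5.0 + 1e-9:
        raise ParameterError(
            "wavelength grid must cover 338-2515 nm at steps of at most 5 nm"
        )
    w = float(np.clip(water_proxy, 0.0, 1.0))
    c = 1.0 / (1.0 + np.exp(-(latent_trait - CANOPY_MIDPOINT) / CANOPY_SCALE))

    soil = soil_reflectance_at(wl)
    vis = 0.04 + 0.08 * (1.0 - 0.5 * c) * np.exp(-(((wl - 550.0) / 35.0) ** 2))
    red_edge = 1.0 / (1.0 + np.exp(-(wl - 715.0) / 13.0))
    veg = vis + (0.50 - vis) * red_edge
    dips = (
        0.25 * np.exp(-(((wl - 970.0) / 45.0) ** 2))
        + 0.15 * np.exp(-(((wl - 1200.0) / 70.0) ** 2))
        + 0.65 * np.exp(-(((wl - 1450.0) / 90.0) ** 2))
        + 0.75 * np.exp(-(((wl - 1940.0) / 110.0) ** 2))
    )
    veg = veg * (1.0 - w * dips)
    veg = veg * np.where(wl > 1300.0, np.exp(-(wl - 1300.0) / 4000.0), 1.0)

    refl = (1.0 - c) * soil + c * veg
    if noise_sd > 0:
        r = rng if rng is not None else np.random.default_rng(seed)
        refl = refl + r.normal(0.0, noise_sd, len(wl))
    refl = np.clip(refl, 0.0, 1.2)
    return CanopySpectrum(wl, refl, chlorophyll_proxy=float(c), water_proxy=w)


# --------------------------------------------------------------------------
# sensors and observation channels
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorModel:
    """Observation-channel model for one platform.

    ``window_hours`` is the half-width of the admissible collection window
    around solar noon (a "six-hour window of solar noon" is
    ``window_hours=3``). ``drift_amplitude`` is the fractional illumination
    loss per hour from solar noon at the 800 nm reference wavelength;
    with ``spectral_drift`` the loss scales linearly with wavelength.
    UAS broadband output is raw digital numbers (DN); the other platforms
    report reflectance directly.
    """

    platform: str
    band_centers: tuple[float, ...] = DEFAULT_BAND_CENTERS
    band_width: float = 50.0
    dn_gain: float = 1.0
    dn_offset: float = 0.0
    noise_sd: float = 0.0
    window_hours: float = 2.0
    drift_amplitude: float = 0.0
    drift_spectral_slope: float = 0.0
    drift_reference_nm: float = 800.0
    drift_slope_width_nm: float = 400.0
    illum_noise_sd: float = 0.0
    illum_tilt_sd: float = 0.0
    illum_chroma_sd: float = 0.0
    illum_chroma_scale_nm: float = 120.0
    #: optional spectral mixing per channel: band center -> ((center, weight),
    #: ...); weights should sum to 1. Models filter leakage, e.g. a "blue"
    #: channel dominated by near-infrared response on cameras whose NIR is
    #: later reconstructed with quantum-efficiency coefficients.
    band_mixtures: dict | None = None

    def __post_init__(self) -> None:
        if self.window_hours <= 0:
            raise ParameterError("window_hours must be > 0")
        if not 0.0 <= self.drift_amplitude < 1.0:
            raise ParameterError("drift_amplitude must be in [0, 1)")

    def drift_multiplier(self, time_offset_hours: float, wavelength) -> np.ndarray:
        """Multiplicative illumination factor, exactly 1 at solar noon.

        The intensity part ``1 - a * |t|`` is common to all wavelengths (and
        cancels in band-ratio indices); the spectral part tilts the factor
        around the reference wavelength by ``s * |t|`` per slope width,
        modelling the reddening of incident light and the band-dependent
        canopy BRDF response as the sun moves off zenith.
        """
        wl = np.asarray(wavelength, dtype=float)
        t = abs(time_offset_hours)
        weight = np.clip(
            (wl - self.drift_reference_nm) / self.drift_slope_width_nm, -1.0, 1.0
        )
        intensity = max(1.0 - self.drift_amplitude * t, 0.0)
        return np.maximum(
            intensity * (1.0 + self.drift_spectral_slope * weight * t), 0.0
        )

    def illumination_factor(
        self,
        time_offset_hours: float,
        wavelength,
        rng: np.random.Generator | None,
    ) -> np.ndarray:
        """Stochastic illumination error accrued since the noon calibration.

        Illumination random-walks away from the state captured by the last
        white-panel calibration (cloud haze, solar intensity), so a single
        observation at ``t`` hours from solar noon carries a multiplicative
        intensity error and a spectral-tilt error, each with standard
        deviation growing as ``sqrt(|t|)``. Exactly 1 at solar noon or when
        both error scales are zero.
        """
        wl = np.asarray(wavelength, dtype=float)
        t = abs(time_offset_hours)
        sds = (self.illum_noise_sd, self.illum_tilt_sd, self.illum_chroma_sd)
        if t == 0.0 or all(s == 0.0 for s in sds):
            return np.ones_like(wl)
        if rng is None:
            rng = np.random.default_rng()
        u = rng.normal(0.0, self.illum_noise_sd * np.sqrt(t))
        v = rng.normal(0.0, self.illum_tilt_sd * np.sqrt(t))
        weight = np.clip(
            (wl - self.drift_reference_nm) / self.drift_slope_width_nm, -1.0, 1.0
        )
        factor = (1.0 + u) * (1.0 + v * weight)
        if self.illum_chroma_sd > 0.0:
            # smooth chromatic error: anchors every correlation length,
            # linearly interpolated, so nearby bands move together while
            # red and NIR decorrelate
            anchors = np.arange(300.0, 2650.0, self.illum_chroma_scale_nm)
            draws = rng.normal(0.0, self.illum_chroma_sd * np.sqrt(t), len(anchors))
            factor = factor * (1.0 + np.interp(wl, anchors, draws))
        return np.maximum(factor, 0.0)

    @property
    def emits_dn(self) -> bool:
        return self.platform == UAS_BROADBAND


def uas_sensor(**overrides) -> SensorModel:
    """UAS broadband camera: DN output, four-hour window of solar noon."""
    base = SensorModel(
        platform=UAS_BROADBAND,
        dn_gain=1000.0,
        dn_offset=80.0,
        noise_sd=4.0,
        window_hours=2.0,
        drift_amplitude=0.05,
        drift_spectral_slope=0.05,
        illum_noise_sd=0.05,
        illum_tilt_sd=0.10,
        illum_chroma_sd=0.05,
    )
    return replace(base, **overrides) if overrides else base


def radiometer_sensor(**overrides) -> SensorModel:
    """Handheld broadband radiometer: reflectance output, six-hour window."""
    base = SensorModel(
        platform=RADIOMETER_BROADBAND,
        noise_sd=0.004,
        window_hours=3.0,
        drift_amplitude=0.05,
        drift_spectral_slope=0.05,
        illum_noise_sd=0.05,
        illum_tilt_sd=0.10,
        illum_chroma_sd=0.05,
    )
    return replace(base, **overrides) if overrides else base


def hyperspectral_sensor(**overrides) -> SensorModel:
    """Handheld full-range hyperspectral sensor: curve output, six-hour window."""
    base = SensorModel(
        platform=HYPERSPECTRAL,
        band_centers=(),
        noise_sd=0.003,
        window_hours=3.0,
        drift_amplitude=0.05,
        drift_spectral_slope=0.05,
        illum_noise_sd=0.05,
        illum_tilt_sd=0.10,
        illum_chroma_sd=0.05,
    )
    return replace(base, **overrides) if overrides else base


def observe_plot(
    spectrum: CanopySpectrum,
    sensor: SensorModel,
    time_offset_hours: float = 0.0,
    plot_id: str = "plot",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SpectralObservation:
    """Observe one plot through a sensor channel.

    Broadband platforms return, per band, the band-window mean of the true
    spectrum times the drift multiplier, through the DN transfer
    ``gain * value + offset``, plus Gaussian noise. The hyperspectral
    platform returns the full drifted, noisy curve.

    Raises
    ------
    SchedulingError
        If ``|time_offset_hours|`` exceeds the sensor's collection window.
    """
    if abs(time_offset_hours) > sensor.window_hours:
        raise SchedulingError(
            f"time offset {time_offset_hours:+.2f} h outside "
            f"±{sensor.window_hours} h collection window"
        )
    r = rng if rng is not None else np.random.default_rng(seed)

    if sensor.platform == HYPERSPECTRAL:
        drift = sensor.drift_multiplier(time_offset_hours, spectrum.wavelengths)
        drift = drift * sensor.illumination_factor(
            time_offset_hours, spectrum.wavelengths, r
        )
        refl = spectrum.reflectance * drift
        if sensor.noise_sd > 0:
            refl = refl + r.normal(0.0, sensor.noise_sd, len(refl))
        curve = pd.DataFrame(
            {"wavelength": spectrum.wavelengths, "reflectance": refl}
        )
        return SpectralObservation(
            plot_id=plot_id,
            platform=sensor.platform,
            curve=curve,
            timestamp_offset_hours=time_offset_hours,
        )

    # drift and illumination act on the light itself, so for mixed channels
    # they are applied at each component wavelength before mixing
    components: dict[float, tuple[tuple[float, float], ...]] = {}
    for center in sensor.band_centers:
        if sensor.band_mixtures and center in sensor.band_mixtures:
            components[center] = tuple(sensor.band_mixtures[center])
        else:
            components[center] = ((center, 1.0),)
    comp_centers = np.array(sorted({c for parts in components.values() for c, _ in parts}))
    illum = sensor.illumination_factor(time_offset_hours, comp_centers, r)
    factor = {
        c: float(sensor.drift_multiplier(time_offset_hours, c)) * float(f)
        for c, f in zip(comp_centers, illum)
    }
    values: dict[float, float] = {}
    for center in sensor.band_centers:
        v = sensor.dn_offset
        for c, w in components[center]:
            mean = narrowband_to_broadband(
                spectrum.wavelengths, spectrum.reflectance, c, sensor.band_width
            )
            v += w * mean * factor[c] * sensor.dn_gain
        if sensor.noise_sd > 0:
            v += float(r.normal(0.0, sensor.noise_sd))
        values[center] = v
    return SpectralObservation(
        plot_id=plot_id,
        platform=sensor.platform,
        band_values=values,
        timestamp_offset_hours=time_offset_hours,
        is_dn=sensor.emits_dn,
        qc_flag="uncalibrated_dn" if sensor.emits_dn else "ok",
    )


# --------------------------------------------------------------------------
# calibration panels
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelSet:
    """Spectrally flat calibration panels with known reflectance."""

    reflectances: tuple[float, ...]

    def __post_init__(self) -> None:
        r = self.reflectances
        if len(r) == 0:
            raise ParameterError("panel set must contain at least one panel")
        if any(not 0.02 <= v <= 0.85 for v in r):
            raise ParameterError("panel reflectances must lie in [0.02, 0.85]")
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ParameterError("panel reflectances must be strictly increasing")

    @property
    def panel_ids(self) -> list[str]:
        return [f"panel_{i + 1}" for i in range(len(self.reflectances))]

    def truth_table(self, band_centers) -> pd.DataFrame:
        rows = [
            {"panel_id": pid, "band": band_column(c), "true_reflectance": refl}
            for pid, refl in zip(self.panel_ids, self.reflectances)
            for c in band_centers
        ]
        return pd.DataFrame(rows)


def default_panel_set() -> PanelSet:
    """Five panels spanning 2%-85% reflectance (multi-panel strategy)."""
    return PanelSet((0.02, 0.10, 0.25, 0.50, 0.85))


def single_panel_set() -> PanelSet:
    """One 85% panel (single-panel strategy)."""
    return PanelSet((0.85,))


def observe_panels(
    panel_set: PanelSet,
    sensor: SensorModel,
    time_offset_hours: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Observe calibration panels through the same channel model as plots.

    Returns a long table with columns ``panel_id``, ``band``,
    ``true_reflectance``, ``dn``.
    """
    if abs(time_offset_hours) > sensor.window_hours:
        raise SchedulingError(
            f"time offset {time_offset_hours:+.2f} h outside panel window"
        )
    r = rng if rng is not None else np.random.default_rng(seed)
    rows = []
    centers = np.asarray(sensor.band_centers, dtype=float)
    for pid, refl in zip(panel_set.panel_ids, panel_set.reflectances):
        illum = sensor.illumination_factor(time_offset_hours, centers, r)
        for k, center in enumerate(sensor.band_centers):
            drift = float(sensor.drift_multiplier(time_offset_hours, center)) * float(illum[k])
            dn = refl * drift * sensor.dn_gain + sensor.dn_offset
            if sensor.noise_sd > 0:
                dn += float(r.normal(0.0, sensor.noise_sd))
            rows.append(
                {
                    "panel_id": pid,
                    "band": band_column(center),
                    "true_reflectance": refl,
                    "dn": dn,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# orthomosaic
# --------------------------------------------------------------------------

def simulate_orthomosaic(
    plot_values: pd.DataFrame,
    *,
    band_centers=None,
    plot_width: float = 1.5,
    plot_length: float = 3.5,
    alley_x: float = 0.3,
    alley_y: float = 0.6,
    margin: float = 2.0,
    gsd: float = 0.1,
    inset: float = 0.2,
    plots_per_row: int | None = None,
    positions: dict | None = None,
    soil_reflectance: dict | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[Raster, list]:
    """Render plot band values into a georeferenced multi-band raster.

    Each plot occupies a ``plot_width x plot_length`` m footprint (1.5 x 3.5
    m default) laid out on a regular grid with alleys; pixels whose centers
    fall inside a footprint carry that plot's band values (plus optional
    Gaussian noise), all other pixels carry the flat soil spectrum. The
    returned polygons are the footprints inset by ``inset`` m on every side,
    so border pixels are excluded from zonal extraction.

    Parameters
    ----------
    plot_values : DataFrame
        ``plot_id`` plus one ``R<center>`` column per band (reflectance or DN).
    positions : dict, optional
        Explicit ``plot_id -> (x_left, y_top)`` footprint anchors (map
        units). Footprints must not overlap.

    Raises
    ------
    LayoutError
        If ``gsd > 0.25`` m (plots would span fewer than 6 x 14 pixels) or
        explicit footprints overlap.
    """
    if gsd > 0.25:
        raise LayoutError("ground-sampling distance must be <= 0.25 m")
    if band_centers is None:
        band_centers = [
            float(c[1:]) for c in plot_values.columns if c.startswith("R")
        ]
    cols_needed = [band_column(c) for c in band_centers]
    missing = [c for c in cols_needed if c not in plot_values.columns]
    if missing:
        raise LayoutError(f"plot_values missing band columns: {missing}")

    n = len(plot_values)
    ids = plot_values["plot_id"].tolist()
    if positions is None:
        ncols = plots_per_row or max(1, int(np.ceil(np.sqrt(n))))
        nrows = int(np.ceil(n / ncols))
        positions = {}
        for i, pid in enumerate(ids):
            row, col = divmod(i, ncols)
            x = margin + col * (plot_width + alley_x)
            y_top_off = margin + row * (plot_length + alley_y)
            positions[pid] = (x, y_top_off)
        height = 2 * margin + nrows * (plot_length + alley_y) - alley_y
        width = 2 * margin + ncols * (plot_width + alley_x) - alley_x
    else:
        xs = [p[0] for p in positions.values()]
        ys = [p[1] for p in positions.values()]
        width = max(xs) + plot_width + margin
        height = max(ys) + plot_length + margin

    footprints = {
        pid: box(x, height - y - plot_length, x + plot_width, height - y)
        for pid, (x, y) in positions.items()
    }
    geoms = list(footprints.values())
    tree = STRtree(geoms)
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            if j != i and g.intersection(geoms[j]).area > 1e-12:
                raise LayoutError("plot footprints overlap")

    n_rows_px = int(np.ceil(height / gsd))
    n_cols_px = int(np.ceil(width / gsd))
    raster = Raster(
        np.empty((len(band_centers), n_rows_px, n_cols_px)),
        tuple(band_centers),
        x_origin=0.0,
        y_origin=n_rows_px * gsd,
        pixel_size=gsd,
    )

    if soil_reflectance is None:
        soil_reflectance = {
            c: float(soil_reflectance_at(np.array([c]))[0]) for c in band_centers
        }
    for i, c in enumerate(band_centers):
        raster.data[i].fill(soil_reflectance[float(c)])

    X, Y = raster.pixel_centers()
    table = plot_values.set_index("plot_id")
    for pid, geom in footprints.items():
        xmin, ymin, xmax, ymax = geom.bounds
        sel = (X > xmin) & (X < xmax) & (Y > ymin) & (Y < ymax)
        for i, c in enumerate(band_centers):
            raster.data[i][sel] = table.loc[pid, band_column(c)]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        raster.data += rng.normal(0.0, noise_sd, raster.data.shape)

    polygons = [
        (pid, box(*_inset_bounds(geom.bounds, inset)))
        for pid, geom in footprints.items()
    ]
    return raster, polygons


def _inset_bounds(bounds, inset):
    xmin, ymin, xmax, ymax = bounds
    if xmax - xmin <= 2 * inset or ymax - ymin <= 2 * inset:
        raise LayoutError("inset larger than half the plot footprint")
    return (xmin + inset, ymin + inset, xmax - inset, ymax - inset)
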