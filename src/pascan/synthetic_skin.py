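"""Synthetic fingertip skin, analyte spectra, and glucose/meter models.

This module generates the ground truth that the scanning photoacoustic
forward model probes:

* a 2-D fingertip skin map with periodic friction ridges and eccrine sweat
  pores placed on the ridge tops (gland density ~350 glands/cm^2 on the
  volar distal phalanx),
* mid-infrared component spectra built from Gaussian absorption bands
  (sodium lactate with its characteristic 1070/1105/1140 cm^-1 triplet,
  glucose C-H-O bands in the 1000-1150 cm^-1 window, a broad skin
  baseline, and a broad water/secretion background),
* first-order eccrine secretion kinetics, s(t) = s_max (1 - exp(-t/tau)),
  which saturate after roughly one hour for the default tau = 15 min,
* an oral-glucose-tolerance blood-glucose time course (75 g drink) with a
  Bateman rise-and-decay shape, and
* a hand-held reference-meter error model with multiplicative Gaussian
  noise.

All randomness flows through explicitly passed seeds / generators; there is
no hidden global state, so identical seeds yield identical maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "WavenumberGrid",
    "ComponentSpectrum",
    "Pore",
    "SkinMap",
    "GlucoseProfile",
    "MeterModel",
    "DEFAULT_BANDS",
    "make_wavenumber_grid",
    "component_spectrum",
    "generate_skin_map",
    "secretion_level",
    "ogtt_glucose_profile",
    "reference_meter_reading",
]

#: (center cm^-1, Gaussian sigma cm^-1, height per unit concentration)
Band = tuple[float, float, float]

#: Default absorption bands per analyte, in arbitrary units per unit
#: concentration.  Sodium lactate carries the 1070/1105/1140 cm^-1 triplet
#: seen in eccrine secretion; the glucose bands sit in the C-H-O
#: stretching/bending window (800-1200 cm^-1); skin baseline and water are
#: broad, featureless backgrounds.
DEFAULT_BANDS: dict[str, tuple[Band, ...]] = {
    "glucose": ((1035.0, 25.0, 1.00), (1080.0, 25.0, 0.85), (1110.0, 25.0, 0.65)),
    "sodium_lactate": ((1070.0, 12.0, 1.00), (1105.0, 11.0, 0.82), (1140.0, 12.0, 0.90)),
    "skin_baseline": ((1000.0, 120.0, 0.55), (1180.0, 90.0, 0.35)),
    "water": ((1040.0, 170.0, 1.20),),
}


def _rng(seed) -> np.random.Generator:
    """Accept an int, SeedSequence, Generator, or None and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Wavenumber grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform mid-infrared sampling grid.

    The point count follows the instrument's convention: ``floor((stop -
    start) / step)`` points at ``start + k * step``; a 950-1240 cm^-1 sweep
    at 1.38 cm^-1 per point therefore has 210 points, the last one at
    1238.42 cm^-1.
    """

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if self.stop <= self.start:
            raise ValueError(
                f"empty range: stop ({self.stop}) must exceed start ({self.start})"
            )
        if len(self) < 1:
            raise ValueError("range shorter than one step yields an empty grid")

    def __len__(self) -> int:
        return int(math.floor((self.stop - self.start) / self.step + 1e-9))

    @property
    def points(self) -> np.ndarray:
        return self.start + self.step * np.arange(len(self), dtype=float)

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.points - wavenumber)))


def make_wavenumber_grid(start: float, stop: float, step: float) -> WavenumberGrid:
    """Build a :class:`WavenumberGrid`; rejects non-positive steps and empty ranges."""
    return WavenumberGrid(start, stop, step)


# ---------------------------------------------------------------------------
# Component spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentSpectrum:
    """Unit absorption of one analyte sampled on a :class:`WavenumberGrid`."""

    analyte: str
    grid: WavenumberGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.grid),):
            raise ValueError(
                f"values length {values.shape} does not match grid length {len(self.grid)}"
            )
        if np.any(values < 0):
            raise ValueError("component spectra are non-negative")


def evaluate_bands(points: np.ndarray, bands: Sequence[Band]) -> np.ndarray:
    """Sum of Gaussian bands ``h * exp(-(nu - c)^2 / (2 w^2))`` on ``points``."""
    points = np.asarray(points, dtype=float)
    out = np.zeros_like(points)
    for center, width, height in bands:
        out += height * np.exp(-((points - center) ** 2) / (2.0 * width**2))
    return out


def component_spectrum(
    analyte: str,
    grid: WavenumberGrid,
    bands: Sequence[Band] | None = None,
) -> ComponentSpectrum:
    """Evaluate an analyte's Gaussian-band spectrum on ``grid``.

    ``bands`` overrides the library defaults; an unknown analyte without an
    explicit band list is rejected.
    """
    if bands is None:
        try:
            bands = DEFAULT_BANDS[analyte]
        except KeyError:
            raise ValueError(
                f"unknown analyte {analyte!r} and no band list given; "
                f"known analytes: {sorted(DEFAULT_BANDS)}"
            ) from None
    return ComponentSpectrum(analyte, grid, evaluate_bands(grid.points, bands))


# ---------------------------------------------------------------------------
# Secretion kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pore:
    """One eccrine sweat pore: position, saturation amplitude, kinetics.

    ``sigma`` is the lateral Gaussian footprint (um) of the secretion film
    around the duct opening.
    """

    x: float
    y: float
    s_max: float
    tau: float
    sigma: float = 35.0


def secretion_level(t, pore) -> np.ndarray | float:
    """First-order secretion build-up after hand washing.

    ``s(t) = s_max * (1 - exp(-t / tau))`` with t in minutes from the
    washed-skin state.  Saturates (>98 %) after ~4 tau, i.e. about one hour
    for the default tau = 15 min.  Accepts a :class:`Pore` or any mapping
    with ``s_max``/``tau`` keys; t may be scalar or array.
    """
    if isinstance(pore, Pore):
        s_max, tau = pore.s_max, pore.tau
    else:
        s_max, tau = pore["s_max"], pore["tau"]
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0 (t = 0 is the post-hand-washing state)")
    out = s_max * (1.0 - np.exp(-t_arr / tau))
    return out if t_arr.ndim else float(out)


# ---------------------------------------------------------------------------
# Glucose profile and reference meter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlucoseProfile:
    """Blood-glucose time course of one oral-glucose-tolerance test."""

    times: np.ndarray      # minutes from experiment start
    values: np.ndarray     # mg/dl
    intake_time: float     # minutes (glucose drink)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(values <= 0):
            raise ValueError("glucose values must be positive")

    def value_at(self, t) -> np.ndarray | float:
        out = np.interp(t, self.times, self.values)
        return out if np.ndim(t) else float(out)


def ogtt_glucose_profile(
    duration: float = 120.0,
    intake_time: float = 20.0,
    baseline: float = 90.0,
    peak_rise: float = 60.0,
    seed=None,
    *,
    cadence: float = 5.0,
    absorption_rate: float = 0.040,
    elimination_rate: float = 1.0 / 70.0,
    drift_sd: float = 0.5,
) -> GlucoseProfile:
    """Simulate an oral-glucose-tolerance blood-glucose time course.

    Pre-intake the profile sits at ``baseline`` plus a small random-walk
    drift; after the 75-g drink at ``intake_time`` it follows a Bateman
    rise-and-decay, ``exp(-kb t') - exp(-ka t')``, scaled so its maximum is
    ``peak_rise`` mg/dl above baseline.  The default rate constants put the
    peak ~40 min after intake.  Sampled on the reference cadence (default
    every 5 min).
    """
    if baseline <= 0:
        raise ValueError("baseline glucose must be positive")
    if intake_time >= duration:
        raise ValueError("intake_time must precede the end of the experiment")
    ka, kb = absorption_rate, elimination_rate
    if ka <= kb:
        raise ValueError("absorption_rate must exceed elimination_rate")
    rng = _rng(seed)
    times = np.arange(0.0, duration + cadence / 2.0, cadence)
    # slow physiological drift: smoothed random walk, a few mg/dl over 2 h
    steps = rng.normal(0.0, drift_sd, size=times.size)
    steps[0] = 0.0
    drift = np.convolve(np.cumsum(steps), np.ones(3) / 3.0, mode="same")
    t_post = np.clip(times - intake_time, 0.0, None)
    bateman = np.where(t_post > 0, np.exp(-kb * t_post) - np.exp(-ka * t_post), 0.0)
    t_peak = math.log(ka / kb) / (ka - kb)
    bateman_peak = math.exp(-kb * t_peak) - math.exp(-ka * t_peak)
    values = baseline + drift + peak_rise * bateman / bateman_peak
    return GlucoseProfile(times=times, values=values, intake_time=intake_time)


@dataclass(frozen=True)
class MeterModel:
    """Reference glucose meter with multiplicative Gaussian error.

    The default ``sigma_rel = 0.05`` places 68.3 % of readings within 5 % of
    truth, matching the meter's stated 68 % accuracy at the 5 % error grid.
    The implied 95.4 % within 10 % is optimistic against the stated 93 %;
    the single-parameter model accepts that mismatch.
    """

    sigma_rel: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")


def reference_meter_reading(true_glucose, meter: MeterModel, seed=None):
    """Draw reference-meter readings: ``g * (1 + eps)``, eps ~ N(0, sigma_rel)."""
    g = np.asarray(true_glucose, dtype=float)
    if np.any(g <= 0):
        raise ValueError("true glucose must be positive")
    rng = _rng(seed)
    eps = rng.normal(0.0, meter.sigma_rel, size=g.shape)
    out = g * (1.0 + eps)
    return out if g.ndim else float(out)


# ---------------------------------------------------------------------------
# Skin map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SkinMap:
    """Ground-truth fingertip patch probed by the instrument.

    The absorption at a point is a linear mixture evaluated at an effective
    probing depth:

    ``a(x, y, nu, t) = c(x, y) * [ s(x, y, t) * S_secretion(nu)
                                   + exp(-kappa s) * sum_a conc_a S_a(nu) ]``

    where ``c`` is the skin/cell acoustic-coupling factor (ridge tops
    contact the cell, valleys couple at ``coupling_floor``), ``s`` is the
    eccrine secretion film built up by the pores, ``S_secretion`` mixes the
    sodium-lactate triplet with a broad water band, and the exponential
    models the film damping the sub-surface (interstitial-fluid) glucose
    and skin-baseline absorption.  Glucose concentration follows the
    attached blood-glucose profile scaled by ``glucose_per_mgdl``.
    """

    extent: tuple[float, float]
    ridge_period: float
    pattern: str = "linear"
    phase: float = 0.0
    pores: tuple[Pore, ...] = ()
    concentrations: Mapping[str, float] = field(
        default_factory=lambda: {"skin_baseline": 1.0}
    )
    glucose_profile: GlucoseProfile | None = None
    constant_glucose: float = 90.0
    glucose_per_mgdl: float = 3e-4
    coupling_floor: float = 0.35
    occlusion: float = 1.0
    secretion_noise: float = 0.10
    secretion_water_ratio: float = 1.0
    spectra_bands: Mapping[str, tuple[Band, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    ridge_top_threshold: float = 0.8

    # -- geometry ----------------------------------------------------------

    def ridge_height(self, x, y) -> np.ndarray:
        """Normalized ridge topography in [0, 1] (1 = ridge top, 0 = valley floor)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.pattern == "linear":
            coord = x
        elif self.pattern == "u":
            # concentric arcs around a center below the field: U-shaped ridges
            cx, cy = self.extent[0] / 2.0, -self.extent[1] / 4.0
            coord = np.hypot(x - cx, y - cy)
        else:
            raise ValueError(f"unknown ridge pattern {self.pattern!r}")
        return 0.5 * (1.0 + np.cos(2.0 * np.pi * coord / self.ridge_period + self.phase))

    def coupling(self, x, y) -> np.ndarray:
        return self.coupling_floor + (1.0 - self.coupling_floor) * self.ridge_height(x, y)

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.extent[0] and 0.0 <= y <= self.extent[1]

    # -- fields ------------------------------------------------------------

    def secretion_field(self, x, y, t: float, pore_factors=None) -> np.ndarray:
        """Secretion film amplitude at time t; optional per-pore multipliers."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape)
        for k, pore in enumerate(self.pores):
            level = secretion_level(t, pore)
            if pore_factors is not None:
                level = level * pore_factors[k]
            d2 = (x - pore.x) ** 2 + (y - pore.y) ** 2
            out += level * np.exp(-d2 / (2.0 * pore.sigma**2))
        return np.clip(out, 0.0, None)

    def glucose_mgdl(self, t: float) -> float:
        if self.glucose_profile is not None:
            return float(self.glucose_profile.value_at(t))
        return self.constant_glucose

    def _component(self, analyte: str, wavenumbers: np.ndarray) -> np.ndarray:
        # analytes absent from the band library contribute zero absorption
        return evaluate_bands(wavenumbers, self.spectra_bands.get(analyte, ()))

    def absorption(self, x, y, wavenumbers, t: float, rng=None) -> np.ndarray:
        """Local absorption, shape ``(*position_shape, n_wavenumbers)``.

        If ``rng`` is given and ``secretion_noise > 0``, one multiplicative
        fluctuation factor per pore is drawn for this call (pulsatile gland
        activity); otherwise secretion is deterministic.
        """
        if isinstance(wavenumbers, WavenumberGrid):
            nu = wavenumbers.points
        else:
            nu = np.atleast_1d(np.asarray(wavenumbers, dtype=float))
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        pore_factors = None
        if rng is not None and self.secretion_noise > 0 and self.pores:
            pore_factors = np.clip(
                1.0 + self.secretion_noise * rng.standard_normal(len(self.pores)),
                0.0,
                None,
            )
        sec = self.secretion_field(x, y, t, pore_factors)[..., None]
        coupling = self.coupling(x, y)[..., None]
        secretion_spec = (
            self._component("sodium_lactate", nu)
            + self.secretion_water_ratio * self._component("water", nu)
        )
        sub = np.zeros_like(nu)
        for analyte, conc in self.concentrations.items():
            sub = sub + conc * self._component(analyte, nu)
        if "glucose" in self.spectra_bands:
            sub = sub + self.glucose_mgdl(t) * self.glucose_per_mgdl * self._component(
                "glucose", nu
            )
        attenuation = np.exp(-self.occlusion * sec)
        return coupling * (sec * secretion_spec + attenuation * sub)


def generate_skin_map(
    extent: tuple[float, float] = (1500.0, 1500.0),
    ridge_period: float = 450.0,
    gland_density: float = 350.0,
    analyte_concentrations: Mapping[str, float] | None = None,
    seed=None,
    *,
    pattern: str = "linear",
    ridge_top_threshold: float = 0.8,
    min_pore_spacing: float = 120.0,
    pore_sigma: float = 35.0,
    s_max_mean: float = 1.2,
    s_max_sd: float = 0.3,
    tau_mean: float = 15.0,
    tau_sd: float = 3.0,
    glucose_profile: GlucoseProfile | None = None,
    coupling_floor: float = 0.35,
    occlusion: float = 1.0,
    secretion_noise: float = 0.10,
    glucose_per_mgdl: float = 3e-4,
    spectra_bands: Mapping[str, tuple[Band, ...]] | None = None,
) -> SkinMap:
    """Generate a fingertip skin map with Poisson-placed ridge-top pores.

    Pore count is Poisson with mean ``gland_density x area``; each pore is
    rejection-sampled onto a ridge top (``ridge_height >= ridge_top_threshold``)
    with a minimum mutual spacing.  A density so high that the spacing cannot
    be honoured is rejected.  Deterministic under a fixed seed.
    """
    if extent[0] <= 0 or extent[1] <= 0:
        raise ValueError("extent must be positive")
    if ridge_period <= 0:
        raise ValueError("ridge_period must be positive")
    if gland_density < 0:
        raise ValueError("gland_density must be >= 0")
    rng = _rng(seed)
    concentrations = dict(analyte_concentrations or {"skin_baseline": 1.0})
    skin = SkinMap(
        extent=tuple(float(v) for v in extent),
        ridge_period=float(ridge_period),
        pattern=pattern,
        concentrations=concentrations,
        glucose_profile=glucose_profile,
        coupling_floor=coupling_floor,
        occlusion=occlusion,
        secretion_noise=secretion_noise,
        glucose_per_mgdl=glucose_per_mgdl,
        spectra_bands=dict(spectra_bands) if spectra_bands is not None else dict(DEFAULT_BANDS),
        ridge_top_threshold=ridge_top_threshold,
    )
    area_cm2 = (extent[0] * 1e-4) * (extent[1] * 1e-4)
    n_pores = int(rng.poisson(gland_density * area_cm2))
    pores: list[Pore] = []
    max_tries = 2000
    for _ in range(n_pores):
        for attempt in range(max_tries):
            px = rng.uniform(0.0, extent[0])
            py = rng.uniform(0.0, extent[1])
            if float(skin.ridge_height(px, py)) < ridge_top_threshold:
                continue
            if any(math.hypot(px - p.x, py - p.y) < min_pore_spacing for p in pores):
                continue
            break
        else:
            raise ValueError(
                f"gland density {gland_density}/cm^2 too high: could not place "
                f"pore {len(pores) + 1} with {min_pore_spacing} um spacing"
            )
        s_max = float(np.clip(rng.normal(s_max_mean, s_max_sd), 0.1 * s_max_mean, None))
        tau = float(np.clip(rng.normal(tau_mean, tau_sd), 3.0, None))
        pores.append(Pore(x=px, y=py, s_max=s_max, tau=tau, sigma=pore_sigma))
    return SkinMap(
        extent=skin.extent,
        ridge_period=skin.ridge_period,
        pattern=skin.pattern,
        phase=skin.phase,
        pores=tuple(pores),
        concentrations=concentrations,
        glucose_profile=glucose_profile,
        constant_glucose=skin.constant_glucose,
        glucose_per_mgdl=glucose_per_mgdl,
        coupling_floor=coupling_floor,
        occlusion=occlusion,
        secretion_noise=secretion_noise,
        secretion_water_ratio=skin.secretion_water_ratio,
        spectra_bands=skin.spectra_bands,
        ridge_top_threshold=ridge_top_threshold,
    )
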