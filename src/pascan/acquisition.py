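"""Forward model of the scanning photoacoustic instrument.

Models the parts of the instrument that shape the recorded signal: the
Gaussian excitation beam (90 um 1/e^2 diameter at focus), the 30x30-pixel
raster at 44 um steps, the 950-1240 cm^-1 wavenumber sweep, the resonant
photoacoustic cell (47.5 kHz, Q = 17) entering as a scalar gain, the
pulse-energy tuning curve of the quantum-cascade laser, and lock-in /
repeat averaging of additive per-pulse noise.  Acoustic wave propagation
beyond the scalar resonance gain is out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .synthetic_skin import SkinMap, WavenumberGrid, _rng

__all__ = [
    "InstrumentConfig",
    "BeamKernel",
    "PAImage",
    "Spectrum",
    "beam_kernel",
    "raster_scan",
    "resolution_contrast",
    "min_resolvable_linewidth",
    "acquire_spectrum",
    "normalize_by_pulse_energy",
    "cell_gain",
    "laser_accounting",
]


@dataclass(frozen=True)
class InstrumentConfig:
    """Instrument parameters; defaults mirror the measurement conditions."""

    beam_diameter: float = 90.0          # um, 1/e^2 intensity diameter
    focal_distance_mm: float = 50.4      # informational
    n_pixels: int = 30                   # per axis
    step: float = 44.0                   # um raster step
    imaging_wavenumber: float = 1040.0   # cm^-1 for 2-D position scans
    rep_rate: float = 47_500.0           # Hz
    pulse_width_ns: float = 500.0
    lockin_tc_ms: float = 30.0
    n_repeats: int = 16                  # averaged wavenumber sweeps
    cell_f0: float = 47_500.0            # Hz, cell/microphone resonance
    cell_q: float = 17.0
    noise_sigma: float = 150.0           # per-pulse additive signal noise (a.u.)
    pulse_energy_peak_nj: float = 44.2
    pulse_energy_center: float = 1000.0  # cm^-1
    pulse_energy_width: float = 200.0    # cm^-1 Gaussian width of tuning curve
    energy_domain: tuple[float, float] = (900.0, 1250.0)
    # optional tabulated curve (wavenumbers, energies in nJ) imported from CSV
    pulse_energy_table: tuple[tuple[float, ...], tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        positive = {
            "beam_diameter": self.beam_diameter,
            "n_pixels": self.n_pixels,
            "step": self.step,
            "rep_rate": self.rep_rate,
            "pulse_width_ns": self.pulse_width_ns,
            "lockin_tc_ms": self.lockin_tc_ms,
            "n_repeats": self.n_repeats,
            "cell_f0": self.cell_f0,
            "cell_q": self.cell_q,
            "pulse_energy_peak_nj": self.pulse_energy_peak_nj,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def pulse_energy(self, wavenumbers) -> np.ndarray:
        """Pulse energy (nJ) at the requested wavenumbers.

        Default is a smooth synthetic tuning curve peaking at 1000 cm^-1
        with the printed 44.2 nJ maximum; a tabulated curve (CSV import)
        takes precedence.  Wavenumbers outside the curve domain are
        rejected.
        """
        nu = np.atleast_1d(np.asarray(wavenumbers, dtype=float))
        if self.pulse_energy_table is not None:
            tab_nu = np.asarray(self.pulse_energy_table[0], dtype=float)
            tab_e = np.asarray(self.pulse_energy_table[1], dtype=float)
            if np.any(nu < tab_nu.min()) or np.any(nu > tab_nu.max()):
                raise ValueError("wavenumber outside the tabulated pulse-energy curve")
            return np.interp(nu, tab_nu, tab_e)
        lo, hi = self.energy_domain
        if np.any(nu < lo) or np.any(nu > hi):
            raise ValueError(
                f"wavenumber outside the laser tuning range {self.energy_domain}"
            )
        return self.pulse_energy_peak_nj * np.exp(
            -(((nu - self.pulse_energy_center) / self.pulse_energy_width) ** 2)
        )

    @property
    def pulses_per_tc(self) -> int:
        return int(round(self.rep_rate * self.lockin_tc_ms * 1e-3))


@dataclass(frozen=True)
class BeamKernel:
    """Discretized beam-intensity kernel: weights on a square offset grid."""

    weights: np.ndarray   # (k, k), sums to 1
    offsets: np.ndarray   # (k,) um, shared by both axes
    pitch: float          # um


@dataclass(frozen=True)
class PAImage:
    """One raster-scan photoacoustic image at a single wavenumber."""

    values: np.ndarray          # (n, n) signal, row = y, col = x
    pixel_pitch: float          # um
    origin: tuple[float, float]  # um offset of the scan window
    wavenumber: float           # cm^-1

    def pixel_center_um(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin[0] + self.pixel_pitch * (col + 0.5),
            self.origin[1] + self.pixel_pitch * (row + 0.5),
        )

    @property
    def field_of_view_mm(self) -> float:
        return self.values.shape[1] * self.pixel_pitch / 1000.0


@dataclass(frozen=True)
class Spectrum:
    """Signal versus wavenumber at one probing position."""

    grid: WavenumberGrid
    values: np.ndarray
    position: tuple[float, float] | None = None
    time: float | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.grid),):
            raise ValueError("spectrum length must match its grid")


# ---------------------------------------------------------------------------
# Beam kernel and generic scanning
# ---------------------------------------------------------------------------

def beam_kernel(config: InstrumentConfig, pixel_pitch: float) -> BeamKernel:
    """Rotationally symmetric Gaussian intensity kernel.

    The 1/e^2 intensity diameter equals ``config.beam_diameter`` (sigma =
    D/4); the kernel is discretized at ``pixel_pitch``, truncated at >= 3
    sigma, and sum-normalized to 1.  A pitch coarser than the beam emits an
    undersampling warning rather than an error.
    """
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be positive")
    if pixel_pitch > config.beam_diameter:
        warnings.warn(
            f"pixel pitch {pixel_pitch} um undersamples the {config.beam_diameter} um beam",
            stacklevel=2,
        )
    sigma = config.beam_diameter / 4.0
    radius = max(1, int(math.ceil(3.0 * sigma / pixel_pitch)))
    offsets = pixel_pitch * np.arange(-radius, radius + 1, dtype=float)
    dx, dy = np.meshgrid(offsets, offsets, indexing="xy")
    weights = np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))
    weights /= weights.sum()
    return BeamKernel(weights=weights, offsets=offsets, pitch=pixel_pitch)


def _beam_average(absorb_fn, xs, ys, kernel: BeamKernel) -> np.ndarray:
    """Beam-weighted absorption at positions (xs[i], ys[i]).

    ``absorb_fn(x, y)`` must accept flat coordinate arrays and return an
    array whose leading axis matches them (trailing axes, e.g. wavenumber,
    are preserved).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    ox, oy = np.meshgrid(kernel.offsets, kernel.offsets, indexing="xy")
    sample_x = xs[:, None] + ox.ravel()[None, :]
    sample_y = ys[:, None] + oy.ravel()[None, :]
    vals = absorb_fn(sample_x.ravel(), sample_y.ravel())
    vals = vals.reshape(xs.size, kernel.weights.size, -1)
    return np.einsum("pk...,k->p...", vals, kernel.weights.ravel())


# ---------------------------------------------------------------------------
# Imaging
# ---------------------------------------------------------------------------

def raster_scan(
    skin: SkinMap,
    t: float,
    wavenumber: float | None = None,
    config: InstrumentConfig = InstrumentConfig(),
    seed=None,
    *,
    origin: tuple[float, float] | None = None,
) -> PAImage:
    """Simulate a 2-D position scan at a single wavenumber.

    Pixel value = cell resonance gain x pulse energy x (beam kernel
    convolved with the local absorption) plus additive noise whose standard
    deviation is reduced by sqrt(pulses per lock-in dwell).  Pixel centers
    sit at ``origin + step * (k + 1/2)``; the default origin centers the
    scan window in the skin map.
    """
    if wavenumber is None:
        wavenumber = config.imaging_wavenumber
    energy = float(config.pulse_energy(wavenumber)[0])
    kernel = beam_kernel(config, config.step)
    span = config.n_pixels * config.step
    if origin is None:
        origin = ((skin.extent[0] - span) / 2.0, (skin.extent[1] - span) / 2.0)
    margin = kernel.offsets.max()
    if (
        origin[0] - margin < 0
        or origin[1] - margin < 0
        or origin[0] + span + margin > skin.extent[0]
        or origin[1] + span + margin > skin.extent[1]
    ):
        raise ValueError("skin map extent does not cover the scan field plus beam margin")
    centers = config.step * (np.arange(config.n_pixels) + 0.5)
    cx, cy = np.meshgrid(origin[0] + centers, origin[1] + centers, indexing="xy")
    rng = _rng(seed)

    def absorb(x, y):
        return skin.absorption(x, y, [wavenumber], t, rng=rng)

    gain = cell_gain(config.rep_rate, config)
    signal = gain * energy * _beam_average(absorb, cx.ravel(), cy.ravel(), kernel)
    values = signal[:, 0].reshape(config.n_pixels, config.n_pixels)
    if config.noise_sigma > 0:
        noise_sd = config.noise_sigma / math.sqrt(config.pulses_per_tc)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return PAImage(
        values=values, pixel_pitch=config.step, origin=tuple(origin), wavenumber=wavenumber
    )


def resolution_contrast(
    line_width: float,
    config: InstrumentConfig = InstrumentConfig(),
    *,
    n_periods: int = 4,
    samples_per_width: int = 6,
) -> float:
    """Modulation contrast of a noiseless scan over an equal line/space target.

    Absorbing bars of the given width alternate with equal non-absorbing
    spaces (the SU-8 resolution fixture analog).  The scan pitch is the
    finer of ``line_width / samples_per_width`` and the beam sigma; the
    contrast is (max - min) / (max + min) of the across-line profile.
    """
    if line_width <= 0:
        raise ValueError("line_width must be positive")
    sigma = config.beam_diameter / 4.0
    pitch = min(line_width / samples_per_width, sigma)
    kernel = beam_kernel(config, pitch)
    period = 2.0 * line_width
    n_samples = int(round(n_periods * period / pitch))
    xs = pitch * (np.arange(n_samples) + 0.5)
    ys = np.zeros_like(xs)

    def bars(x, y):
        return (np.mod(x, period) < line_width).astype(float)[:, None]

    profile = _beam_average(bars, xs, ys, kernel)[:, 0]
    hi, lo = profile.max(), profile.min()
    if hi + lo == 0:
        return 0.0
    return float((hi - lo) / (hi + lo))


def min_resolvable_linewidth(
    config: InstrumentConfig = InstrumentConfig(),
    widths=None,
    threshold: float = 0.10,
) -> float:
    """Smallest tested line width whose modulation contrast reaches ``threshold``.

    Widths are scanned in decreasing order; contrast is monotone in width
    for a fixed beam, so the result is the resolution limit under the
    stated contrast criterion.
    """
    if widths is None:
        widths = np.arange(150.0, 9.0, -5.0)
    resolved = [w for w in widths if resolution_contrast(w, config) >= threshold]
    if not resolved:
        raise ValueError("no tested line width was resolved; extend the width range")
    return float(min(resolved))


# ---------------------------------------------------------------------------
# Spectral acquisition
# ---------------------------------------------------------------------------

def acquire_spectrum(
    skin: SkinMap,
    position: tuple[float, float],
    t: float,
    grid: WavenumberGrid,
    config: InstrumentConfig = InstrumentConfig(),
    seed=None,
) -> Spectrum:
    """Simulate one wavenumber sweep at a fixed probing position.

    Per-wavenumber signal = resonance gain x pulse energy(nu) x
    beam-weighted absorption, plus additive noise with standard deviation
    ``noise_sigma / sqrt(pulses_per_tc * n_repeats)``.  The returned
    spectrum is unnormalized (pulse-energy variation still imprinted).
    """
    if not skin.contains(*position):
        raise ValueError(f"position {position} lies outside the skin map {skin.extent}")
    rng = _rng(seed)
    # fine sub-beam sampling, independent of the raster step
    kernel = beam_kernel(config, config.beam_diameter / 6.0)
    nu = grid.points

    def absorb(x, y):
        return skin.absorption(x, y, nu, t, rng=rng)

    gain = cell_gain(config.rep_rate, config)
    weighted = _beam_average(absorb, [position[0]], [position[1]], kernel)[0]
    values = gain * config.pulse_energy(nu) * weighted
    if config.noise_sigma > 0:
        noise_sd = config.noise_sigma / math.sqrt(config.pulses_per_tc * config.n_repeats)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return Spectrum(grid=grid, values=values, position=tuple(position), time=t)


def normalize_by_pulse_energy(spectrum: Spectrum, config: InstrumentConfig) -> Spectrum:
    """Divide a raw spectrum pointwise by the laser pulse-energy curve."""
    if spectrum.normalized:
        raise ValueError("spectrum is already pulse-energy normalized")
    energy = config.pulse_energy(spectrum.grid.points)
    if np.any(energy <= 0):
        raise ValueError("pulse-energy curve must be strictly positive on the grid")
    return replace(spectrum, values=spectrum.values / energy, normalized=True)


# ---------------------------------------------------------------------------
# Cell resonance and laser accounting
# ---------------------------------------------------------------------------

def cell_gain(f: float, config: InstrumentConfig = InstrumentConfig()) -> float:
    """Lorentzian resonance gain of the photoacoustic cell.

    Peak gain Q at ``cell_f0``; half-power full width ``cell_f0 / cell_Q``
    (about 2.79 kHz for 47.5 kHz / 17).
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    hwhm = config.cell_f0 / (2.0 * config.cell_q)
    return float(config.cell_q / (1.0 + ((f - config.cell_f0) / hwhm) ** 2))


def laser_accounting(config: InstrumentConfig = InstrumentConfig()) -> dict[str, float]:
    """Pulse and power bookkeeping at the reference (peak-energy) wavenumber.

    47.5 kHz x 30 ms -> 1425 pulses per lock-in time constant; 44.2 nJ at
    47.5 kHz -> 2.1 mW average power; 44.2 nJ over 500 ns -> 88.4 mW
    single-pulse power.
    """
    energy_j = config.pulse_energy_peak_nj * 1e-9
    return {
        "pulses_per_tc": float(config.pulses_per_tc),
        "avg_power_mW": energy_j * config.rep_rate * 1e3,
        "peak_power_mW": energy_j / (config.pulse_width_ns * 1e-9) * 1e3,
    }
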