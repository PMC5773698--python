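"""End-to-end glucose correlation experiments on synthetic skin.

Orchestrates the full protocol: hand wash (secretion clock reset), 2-D
position scan at the imaging wavenumber, probe-site selection, paired
spectral + reference-meter acquisitions on the 5-min cadence through an
oral-glucose-tolerance test, a closing position scan to confirm the finger
did not move, per-site PLSR calibration with leave-one-out
cross-validation, and clinical-accuracy evaluation.  The whole pipeline is
a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import evaluation
from .acquisition import (
    InstrumentConfig,
    PAImage,
    acquire_spectrum,
    normalize_by_pulse_energy,
    raster_scan,
)
from .chemometrics import CalibrationSet, CVResult, loo_cv
from .evaluation import EvaluationReport, evaluate_experiment
from .site_selection import SiteSelection, segment_blobs, select_probe_sites
from .synthetic_skin import (
    GlucoseProfile,
    MeterModel,
    SkinMap,
    generate_skin_map,
    make_wavenumber_grid,
    ogtt_glucose_profile,
    reference_meter_reading,
)

__all__ = [
    "SkinParams",
    "GlucoseParams",
    "ProtocolConfig",
    "ChemometricsConfig",
    "ExperimentConfig",
    "SiteResult",
    "ExperimentResult",
    "ReplicateSummary",
    "run_experiment",
    "run_replicates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SkinParams:
    """Arguments forwarded to :func:`pascan.synthetic_skin.generate_skin_map`."""

    extent: tuple[float, float] = (1500.0, 1500.0)
    ridge_period: float = 450.0
    pattern: str = "linear"
    gland_density: float = 350.0
    ridge_top_threshold: float = 0.8
    min_pore_spacing: float = 120.0
    pore_sigma: float = 35.0
    s_max_mean: float = 1.2
    s_max_sd: float = 0.3
    tau_mean: float = 15.0
    tau_sd: float = 3.0
    coupling_floor: float = 0.35
    occlusion: float = 1.0
    secretion_noise: float = 0.10
    glucose_per_mgdl: float = 3e-4
    concentrations: Mapping[str, float] = field(
        default_factory=lambda: {"skin_baseline": 1.0}
    )


@dataclass(frozen=True)
class GlucoseParams:
    """Oral-glucose-tolerance profile and reference-meter settings."""

    baseline: float = 90.0       # mg/dl
    peak_rise: float = 60.0      # mg/dl above baseline
    drift_sd: float = 0.5        # mg/dl random-walk step per cadence
    meter_sigma_rel: float = 0.05


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing of the glucose correlation test (minutes)."""

    duration: float = 120.0
    cadence: float = 5.0        # reference-meter interval
    intake_time: float = 20.0   # glucose drink
    n_pairs: int = 23           # spectrum/reference pairs per site
    image_time: float = 10.0    # position scan after wash/mount/frequency check
    sites: tuple[str, ...] = ("dark", "bright")


@dataclass(frozen=True)
class ChemometricsConfig:
    max_lv: int = 10
    method: str = "plsr"


@dataclass(frozen=True)
class ExperimentConfig:
    skin: SkinParams = field(default_factory=SkinParams)
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    glucose: GlucoseParams = field(default_factory=GlucoseParams)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    chemometrics: ChemometricsConfig = field(default_factory=ChemometricsConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.protocol
        if p.n_pairs < 3:
            raise ValueError("protocol needs at least 3 spectrum/reference pairs")
        if p.cadence <= 0 or abs(p.duration / p.cadence - round(p.duration / p.cadence)) > 1e-9:
            raise ValueError("reference cadence must divide the experiment duration")
        last = p.image_time + (p.n_pairs - 1) * p.cadence
        if last > p.duration + 1e-9:
            raise ValueError(
                f"protocol infeasible: last pair at t={last} min exceeds duration {p.duration}"
            )

    # -- config (de)serialization ------------------------------------------

    def to_dict(self) -> dict:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: encode(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, Mapping):
                return dict(obj)
            return obj

        return encode(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ExperimentConfig":
        def build(klass, section, where):
            fields = {f.name: f for f in dataclasses.fields(klass)}
            unknown = set(section) - set(fields)
            if unknown:
                raise ValueError(
                    f"unknown config key(s) {sorted(unknown)} in section {where!r}"
                )
            kwargs = {}
            for name, value in section.items():
                if isinstance(value, list):
                    value = tuple(value)
                kwargs[name] = value
            return klass(**kwargs)

        sections = {
            "skin": SkinParams,
            "instrument": InstrumentConfig,
            "glucose": GlucoseParams,
            "protocol": ProtocolConfig,
            "chemometrics": ChemometricsConfig,
        }
        unknown = set(data) - set(sections) - {"seed"}
        if unknown:
            raise ValueError(f"unknown top-level config key(s) {sorted(unknown)}")
        kwargs = {"seed": int(data.get("seed", 0))}
        for name, klass in sections.items():
            if name in data:
                kwargs[name] = build(klass, data[name], name)
        return cls(**kwargs)


@dataclass(frozen=True)
class SiteResult:
    """Calibration, cross-validation, and evaluation for one probing site."""

    position_um: tuple[float, float]
    calibration: CalibrationSet
    cv: CVResult
    report: EvaluationReport


@dataclass(frozen=True)
class ExperimentResult:
    config: ExperimentConfig
    glucose_profile: GlucoseProfile
    skin: SkinMap
    site_selection: SiteSelection
    image_before: PAImage
    image_after: PAImage
    displacement_px: float
    sites: dict[str, SiteResult]
    log: tuple[str, ...]


def _build_skin(params: SkinParams, profile: GlucoseProfile, seed) -> SkinMap:
    return generate_skin_map(
        extent=params.extent,
        ridge_period=params.ridge_period,
        gland_density=params.gland_density,
        analyte_concentrations=dict(params.concentrations),
        seed=seed,
        pattern=params.pattern,
        ridge_top_threshold=params.ridge_top_threshold,
        min_pore_spacing=params.min_pore_spacing,
        pore_sigma=params.pore_sigma,
        s_max_mean=params.s_max_mean,
        s_max_sd=params.s_max_sd,
        tau_mean=params.tau_mean,
        tau_sd=params.tau_sd,
        glucose_profile=profile,
        coupling_floor=params.coupling_floor,
        occlusion=params.occlusion,
        secretion_noise=params.secretion_noise,
        glucose_per_mgdl=params.glucose_per_mgdl,
    )


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute one full glucose correlation test on synthetic skin.

    Protocol stages mirror the measurement procedure: the secretion clock
    starts at zero at the hand wash; the position scan and site selection
    happen at ``protocol.image_time``; each reference time point yields a
    pulse-energy-normalized 16-repeat spectrum at both sites plus a meter
    reading; a closing scan verifies zero site displacement (the simulated
    finger is fixed); each site is then calibrated with LOO-CV PLSR and
    evaluated.
    """
    p = config.protocol
    log: list[str] = []
    ss = np.random.SeedSequence(config.seed)
    s_prof, s_map, s_img0, s_img1, s_acq, s_meter = ss.spawn(6)

    profile = ogtt_glucose_profile(
        duration=p.duration,
        intake_time=p.intake_time,
        baseline=config.glucose.baseline,
        peak_rise=config.glucose.peak_rise,
        seed=s_prof,
        cadence=p.cadence,
        drift_sd=config.glucose.drift_sd,
    )
    log.append(
        f"glucose profile: baseline {config.glucose.baseline} mg/dl, "
        f"rise {config.glucose.peak_rise} mg/dl, intake at {p.intake_time} min"
    )
    skin = _build_skin(config.skin, profile, s_map)
    log.append(f"skin map: {len(skin.pores)} pores over {skin.extent} um")

    grid = make_wavenumber_grid(950.0, 1240.0, 1.38)
    instr = config.instrument

    image_before = raster_scan(skin, p.image_time, instr.imaging_wavenumber, instr, s_img0)
    blobs = segment_blobs(image_before)
    selection = select_probe_sites(image_before, blobs)
    log.append(
        f"position scan at t={p.image_time} min, {instr.imaging_wavenumber} cm^-1: "
        f"{blobs.n_blobs} blobs; dark site {selection.dark_px}, bright site "
        f"{selection.bright_px}"
    )

    site_positions = {"dark": selection.dark_um, "bright": selection.bright_um}
    times = p.image_time + p.cadence * np.arange(p.n_pairs)
    meter = MeterModel(sigma_rel=config.glucose.meter_sigma_rel)
    meter_rng = np.random.default_rng(s_meter)
    acq_seeds = iter(s_acq.spawn(p.n_pairs * len(p.sites)))

    y_ref = np.empty(p.n_pairs)
    spectra = {site: [] for site in p.sites}
    for k, t in enumerate(times):
        for site in p.sites:
            raw = acquire_spectrum(
                skin, site_positions[site], float(t), grid, instr, next(acq_seeds)
            )
            spectra[site].append(normalize_by_pulse_energy(raw, instr).values)
        y_ref[k] = reference_meter_reading(profile.value_at(float(t)), meter, meter_rng)
    log.append(f"acquired {p.n_pairs} spectrum/reference pairs per site")

    image_after = raster_scan(skin, float(times[-1]), instr.imaging_wavenumber, instr, s_img1)
    displacement_px = 0.0  # the simulated finger is rigidly fixed
    log.append("closing position scan: site displacement 0.0 px")

    sites: dict[str, SiteResult] = {}
    for site in p.sites:
        X = np.vstack(spectra[site])
        calset = CalibrationSet(
            X=X, y=y_ref, grid=grid,
            metadata={"site": site, "times_min": times.tolist()},
        )
        cv = loo_cv(X, y_ref, config.chemometrics.max_lv, method=config.chemometrics.method)
        report = evaluate_experiment(
            cv.y_cv, y_ref,
            rmsec=cv.rmsec_by_lv[cv.chosen_lv - 1],
            rmsecv=cv.rmsecv_by_lv[cv.chosen_lv - 1],
        )
        sites[site] = SiteResult(
            position_um=site_positions[site], calibration=calset, cv=cv, report=report
        )
        log.append(
            f"{site} site: {cv.chosen_lv} latent variable(s), "
            f"MARD {report.mard:.2f} %, MAD {report.mad:.2f} mg/dl"
        )
    return ExperimentResult(
        config=config,
        glucose_profile=profile,
        skin=skin,
        site_selection=selection,
        image_before=image_before,
        image_after=image_after,
        displacement_px=displacement_px,
        sites=sites,
        log=tuple(log),
    )


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-site MARD/MAD distributions and pooled Clarke tallies."""

    n_reps: int
    mard: dict[str, np.ndarray]
    mad: dict[str, np.ndarray]
    pooled_zone_counts: dict[str, dict[str, int]]
    pooled_zone_fractions: dict[str, dict[str, float]]
    n_pairs_total: int
    results: tuple[ExperimentResult, ...] = ()


def run_replicates(
    config: ExperimentConfig,
    n_reps: int,
    seed=None,
    keep_results: bool = False,
) -> ReplicateSummary:
    """Run independent seeded replicates and pool the clinical metrics.

    The analog of pooling several glucose correlation tests: per-site MARD
    and MAD distributions across replicates, plus a pooled Clarke summary
    over all concatenated (reference, prediction) pairs.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = config.seed if seed is None else int(seed)
    # sequential base seeds; SeedSequence decorrelates the streams downstream,
    # and replicate 0 reproduces run_experiment(config) exactly
    rep_seeds = [(base + k) % 2**31 for k in range(n_reps)]
    sites = config.protocol.sites
    mard_arr = {s: np.empty(n_reps) for s in sites}
    mad_arr = {s: np.empty(n_reps) for s in sites}
    pooled_pairs = {s: ([], []) for s in sites}
    results = []
    for r, s in enumerate(rep_seeds):
        result = run_experiment(replace(config, seed=int(s)))
        for site in sites:
            rep = result.sites[site].report
            mard_arr[site][r] = rep.mard
            mad_arr[site][r] = rep.mad
            pooled_pairs[site][0].extend(result.sites[site].calibration.y)
            pooled_pairs[site][1].extend(result.sites[site].cv.y_cv)
        if keep_results:
            results.append(result)
    counts = {}
    fractions = {}
    for site in sites:
        c, f = evaluation.clarke_summary(pooled_pairs[site][0], pooled_pairs[site][1])
        counts[site], fractions[site] = c, f
    return ReplicateSummary(
        n_reps=n_reps,
        mard=mard_arr,
        mad=mad_arr,
        pooled_zone_counts=counts,
        pooled_zone_fractions=fractions,
        n_pairs_total=n_reps * config.protocol.n_pairs,
        results=tuple(results),
    )
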