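"""Clinical-accuracy metrics: MARD, MAD, and Clarke error-grid analysis.

MARD (mean absolute relative deviation, %) and MAD (mean absolute
difference, mg/dl) summarize agreement between predicted and reference
glucose; their spreads are reported as population standard deviations of
the per-pair deviations (configurable to the sample convention).  The
Clarke error grid classifies each (reference, predicted) pair into zones
A-E: A is clinically accurate (within 20 % of the reference, or both
hypoglycemic below 70 mg/dl), B benign error, C overcorrection, D failure
to detect, E dangerous confusion of hypo- and hyperglycemia.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "EvaluationReport",
    "mard",
    "mad",
    "clarke_zone",
    "clarke_summary",
    "evaluate_experiment",
]

ZONES = ("A", "B", "C", "D", "E")


def _check_pair(y_pred, y_ref):
    y_pred = np.asarray(y_pred, dtype=float)
    y_ref = np.asarray(y_ref, dtype=float)
    if y_pred.shape != y_ref.shape:
        raise ValueError(
            f"length mismatch: {y_pred.shape} predictions vs {y_ref.shape} references"
        )
    return y_pred, y_ref


def _spread(deviations: np.ndarray, ddof: int) -> float:
    if deviations.size <= ddof:
        return 0.0
    return float(np.std(deviations, ddof=ddof))


def mard(y_pred, y_ref, ddof: int = 0) -> tuple[float, float]:
    """Mean absolute relative deviation in %, with the sd of the deviations."""
    y_pred, y_ref = _check_pair(y_pred, y_ref)
    if np.any(y_ref <= 0):
        raise ValueError("reference glucose must be positive for relative deviations")
    ard = np.abs(y_pred - y_ref) / y_ref * 100.0
    return float(ard.mean()), _spread(ard, ddof)


def mad(y_pred, y_ref, ddof: int = 0) -> tuple[float, float]:
    """Mean absolute difference in mg/dl, with the sd of the differences."""
    y_pred, y_ref = _check_pair(y_pred, y_ref)
    ad = np.abs(y_pred - y_ref)
    return float(ad.mean()), _spread(ad, ddof)


def clarke_zone(ref: float, pred: float) -> str:
    """Clarke error-grid zone of one (reference, predicted) pair.

    Uses the standard piecewise boundaries of the 1987 grid, evaluated in
    the precedence order A -> E -> C -> D -> B so boundary overlaps resolve
    deterministically; boundaries are inclusive.
    """
    if ref <= 0 or pred <= 0:
        raise ValueError("glucose values must be positive")
    if (pred <= 70 and ref <= 70) or (0.8 * ref <= pred <= 1.2 * ref):
        return "A"
    if (ref >= 180 and pred <= 70) or (ref <= 70 and pred >= 180):
        return "E"
    if (130 <= ref <= 180 and pred <= 1.4 * ref - 182) or (
        70 <= ref <= 290 and pred >= ref + 110
    ):
        return "C"
    if (ref >= 240 and 70 <= pred <= 180) or (ref <= 70 <= pred <= 180):
        return "D"
    return "B"


def clarke_summary(y_ref, y_pred) -> tuple[dict[str, int], dict[str, float]]:
    """Per-zone tallies and fractions over a list of pairs."""
    y_pred, y_ref = _check_pair(y_pred, y_ref)
    if y_ref.size == 0:
        raise ValueError("clarke_summary requires at least one pair")
    counts = {z: 0 for z in ZONES}
    for r, p in zip(y_ref.ravel(), y_pred.ravel()):
        counts[clarke_zone(float(r), float(p))] += 1
    n = y_ref.size
    fractions = {z: counts[z] / n for z in ZONES}
    return counts, fractions


@dataclass(frozen=True)
class EvaluationReport:
    """Bundle of clinical-accuracy metrics for one calibration experiment."""

    mard: float
    mard_sd: float
    mad: float
    mad_sd: float
    rmsec: float
    rmsecv: float
    zone_counts: Mapping[str, int]
    zone_fractions: Mapping[str, float]
    n_pairs: int

    def __post_init__(self) -> None:
        if sum(self.zone_counts.values()) != self.n_pairs:
            raise ValueError("zone counts must sum to n_pairs")
        if abs(sum(self.zone_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("zone fractions must sum to 1")

    def to_dict(self) -> dict:
        return {
            "mard_percent": self.mard,
            "mard_sd_percent": self.mard_sd,
            "mad_mgdl": self.mad,
            "mad_sd_mgdl": self.mad_sd,
            "rmsec_mgdl": self.rmsec,
            "rmsecv_mgdl": self.rmsecv,
            "zone_counts": dict(self.zone_counts),
            "zone_fractions": dict(self.zone_fractions),
            "n_pairs": self.n_pairs,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EvaluationReport":
        return cls(
            mard=d["mard_percent"],
            mard_sd=d["mard_sd_percent"],
            mad=d["mad_mgdl"],
            mad_sd=d["mad_sd_mgdl"],
            rmsec=d["rmsec_mgdl"],
            rmsecv=d["rmsecv_mgdl"],
            zone_counts={z: int(v) for z, v in d["zone_counts"].items()},
            zone_fractions={z: float(v) for z, v in d["zone_fractions"].items()},
            n_pairs=int(d["n_pairs"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls.from_dict(json.loads(text))

    def to_text(self) -> str:
        lines = [
            f"n pairs          {self.n_pairs}",
            f"MARD             {self.mard:.2f} % (sd {self.mard_sd:.2f} %)",
            f"MAD              {self.mad:.2f} mg/dl (sd {self.mad_sd:.2f} mg/dl)",
            f"RMSEC            {self.rmsec:.2f} mg/dl",
            f"RMSE-CV          {self.rmsecv:.2f} mg/dl",
            "Clarke zones     "
            + "  ".join(
                f"{z}: {self.zone_counts[z]} ({100 * self.zone_fractions[z]:.0f} %)"
                for z in ZONES
            ),
        ]
        return "\n".join(lines)


def evaluate_experiment(y_cv, y_ref, rmsec: float, rmsecv: float) -> EvaluationReport:
    """Assemble MARD, MAD, RMSE, and Clarke-zone tallies into one report."""
    y_cv, y_ref = _check_pair(y_cv, y_ref)
    mard_val, mard_sd = mard(y_cv, y_ref)
    mad_val, mad_sd = mad(y_cv, y_ref)
    counts, fractions = clarke_summary(y_ref, y_cv)
    return EvaluationReport(
        mard=mard_val,
        mard_sd=mard_sd,
        mad=mad_val,
        mad_sd=mad_sd,
        rmsec=float(rmsec),
        rmsecv=float(rmsecv),
        zone_counts=counts,
        zone_fractions=fractions,
        n_pairs=int(y_ref.size),
    )
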