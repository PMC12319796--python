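"""Two-step calibration of the oxygen-transport model against PET OEF.

Step 1 fixes the tissue oxygen tension PtO2 so that the fast-exchange
(k -> infinity) extraction ceiling equals a chosen maximum physiological
OEF; in that limit the transit-time distribution drops out, so the
inversion is the closed-form inverse Hill relation.

Step 2 root-finds the transfer rate constant k per subject so that the
model OEF at the subject's measured (MTT, CTH) matches the subject's PET
OEF in normal-appearing white matter (NAWM), the region least affected by
pathology.  OEF is strictly increasing in k with a finite ceiling, so the
root is unique; the search runs on log10(k) because calibrated values
span roughly an order of magnitude.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .oxygen_transport import (
    ModelConstants,
    limit_extraction,
)
from .transit_distribution import HemodynamicSummary, oef

logger = logging.getLogger("capox")

__all__ = [
    "CalibrationResult",
    "UnreachableTargetError",
    "calibrate_pto2",
    "calibrate_k",
    "calibrate_cohort",
]

#: Bracket for the k search (1/s), generous around the physiological range.
K_BRACKET = (1e-3, 1e6)
#: Convergence requirement on the calibrated OEF residual.
OEF_TOL = 1e-6


class UnreachableTargetError(ValueError):
    """Target OEF at or above the model's extraction ceiling."""

    def __init__(self, target: float, ceiling: float):
        self.target = target
        self.ceiling = ceiling
        super().__init__(
            f"target OEF {target:.4f} is not below the model ceiling "
            f"{ceiling:.4f} (k -> infinity limit)"
        )


@dataclass
class SubjectCalibration:
    subject_id: str
    k: float
    converged: bool
    residual: float


@dataclass
class CalibrationResult:
    """Outcome of the cohort calibration.

    ``k_mean`` is the arithmetic mean over converged subjects; the median
    is carried as a robustness diagnostic.
    """

    pto2: float
    k_per_subject: list[SubjectCalibration]
    k_mean: float
    k_median: float
    k_range: tuple[float, float]
    excluded_subjects: list[dict] = field(default_factory=list)
    target_max_oef: float = float("nan")

    @property
    def n_converged(self) -> int:
        return sum(1 for s in self.k_per_subject if s.converged)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pto2_mmHg"] = d.pop("pto2")
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def calibrate_pto2(target_max_oef: float, constants: ModelConstants) -> float:
    """Tissue tension whose fast-exchange extraction ceiling equals the target.

    Closed form: the ceiling is 1 - S(PtO2)/S_a, so
    S(PtO2) = S_a * (1 - target) and PtO2 = P50 * (S/(1-S))**(1/h).
    """
    if not 0 < target_max_oef < 1:
        raise ValueError(f"target maximum OEF must be in (0, 1), got {target_max_oef}")
    sat = constants.S_a * (1.0 - target_max_oef)
    if not 0 < sat < 1:
        raise ValueError(
            f"target {target_max_oef} requires venous saturation {sat:.4f} "
            "outside (0, 1): infeasible"
        )
    return constants.P50 * (sat / (1.0 - sat)) ** (1.0 / constants.h)


def calibrate_k(
    target_oef: float,
    summary: HemodynamicSummary,
    constants: ModelConstants,
    *,
    bracket: tuple[float, float] = K_BRACKET,
) -> float:
    """Rate constant k (1/s) at which the model OEF matches ``target_oef``.

    ``constants.PtO2`` is held fixed.  Raises
    :class:`UnreachableTargetError` when the target is at or above the
    extraction ceiling, and ``ValueError`` for non-positive targets or a
    target below what the bracket can reach.
    """
    if target_oef <= 0:
        raise ValueError(f"target OEF must be > 0, got {target_oef}")
    ceiling = limit_extraction(constants.PtO2, constants, on_no_gradient="raise")
    if target_oef >= ceiling:
        raise UnreachableTargetError(target_oef, ceiling)

    lo, hi = np.log10(bracket[0]), np.log10(bracket[1])

    def residual(log_k: float) -> float:
        return oef(summary, constants.with_(k=10.0**log_k)) - target_oef

    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo > 0 or r_hi < 0:
        raise ValueError(
            f"target OEF {target_oef:.4f} outside the bracket "
            f"[{bracket[0]:g}, {bracket[1]:g}] 1/s "
            f"(model OEF range [{r_lo + target_oef:.4f}, {r_hi + target_oef:.4f}])"
        )
    log_k = brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return 10.0**log_k


def calibrate_cohort(
    subjects: pd.DataFrame | Sequence[dict],
    target_max_oef: float,
    constants: ModelConstants,
    *,
    roi: str | None = "NAWM",
) -> CalibrationResult:
    """Calibrate PtO2 once and k per subject from NAWM rows of a cohort table.

    ``subjects`` needs columns ``subject_id``, ``mtt_s``, ``cth_s``,
    ``pet_oef`` (and ``roi`` unless ``roi=None``).  Subjects whose PET OEF
    is at/above the ceiling, or whose inputs are invalid, are excluded
    with a recorded reason rather than dropped silently.
    """
    table = pd.DataFrame(subjects)
    if table.empty:
        raise ValueError("empty cohort: nothing to calibrate")
    if roi is not None and "roi" in table.columns:
        table = table[table["roi"] == roi]
        if table.empty:
            raise ValueError(f"no rows with roi == {roi!r}")
    required = {"subject_id", "mtt_s", "cth_s", "pet_oef"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"cohort table is missing columns: {sorted(missing)}")

    pto2 = calibrate_pto2(target_max_oef, constants)
    consts = constants.with_(PtO2=pto2)
    ceiling = limit_extraction(pto2, consts)

    fits: list[SubjectCalibration] = []
    excluded: list[dict] = []
    for row in table.itertuples(index=False):
        sid = str(row.subject_id)
        try:
            summary = HemodynamicSummary(float(row.mtt_s), float(row.cth_s))
        except ValueError as exc:
            excluded.append({"subject_id": sid, "reason": f"invalid hemodynamics: {exc}"})
            continue
        target = float(row.pet_oef)
        if not np.isfinite(target) or target <= 0:
            excluded.append({"subject_id": sid, "reason": f"invalid PET OEF {target}"})
            continue
        if target >= ceiling:
            excluded.append(
                {
                    "subject_id": sid,
                    "reason": f"PET OEF {target:.4f} >= model ceiling {ceiling:.4f}",
                }
            )
            continue
        k = calibrate_k(target, summary, consts)
        residual = abs(oef(summary, consts.with_(k=k)) - target)
        fits.append(SubjectCalibration(sid, k, residual <= OEF_TOL, residual))

    if excluded:
        logger.warning("calibration excluded %d subjects", len(excluded))
    converged = np.array([s.k for s in fits if s.converged])
    if converged.size == 0:
        raise ValueError("no subject converged; cannot summarize cohort k")
    return CalibrationResult(
        pto2=pto2,
        k_per_subject=fits,
        k_mean=float(converged.mean()),
        k_median=float(np.median(converged)),
        k_range=(float(converged.min()), float(converged.max())),
        excluded_subjects=excluded,
        target_max_oef=target_max_oef,
    )
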