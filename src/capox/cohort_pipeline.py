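"""Cohort orchestration: calibrate, estimate, and assess MRI/PET agreement.

Given a per-subject, per-ROI table of hemodynamics and PET OEF, the
pipeline (1) calibrates the model in NAWM, (2) computes model OEF for
every row with the cohort-mean calibrated k, and (3) summarizes
MRI-vs-PET agreement per ROI with Pearson correlation and Bland-Altman
statistics.  Differences are oriented as (MRI - PET).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .oxygen_transport import ModelConstants
from .transit_distribution import add_model_oef
from .calibration import CalibrationResult, calibrate_cohort

logger = logging.getLogger("capox")

__all__ = ["AgreementReport", "pearson", "bland_altman", "agreement", "run_pipeline", "PipelineResult"]


@dataclass(frozen=True)
class AgreementReport:
    """Pearson and Bland-Altman agreement between two OEF series.

    ``bias`` is mean(x - y); the limits of agreement are
    bias -/+ 1.96 * SD(x - y) with the sample (n-1) standard deviation.
    """

    r: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be congruent 1-D series")
    if len(x) < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series contain non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance series")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bland_altman(x, y) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high) of the differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be congruent 1-D series")
    if len(x) < 2:
        raise ValueError("need n >= 2 for limits of agreement")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def agreement(x, y) -> AgreementReport:
    """Full agreement report between series x (MRI) and y (PET)."""
    bias, lo, hi = bland_altman(x, y)
    r, p = pearson(x, y)
    return AgreementReport(r=r, p_value=p, bias=bias, loa_low=lo, loa_high=hi, n=len(np.asarray(x)))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    calibration: CalibrationResult | None
    table: pd.DataFrame
    agreement: dict[str, AgreementReport]


REQUIRED_COLUMNS = {"subject_id", "roi", "mtt_s", "cth_s"}


def run_pipeline(
    roi_table: pd.DataFrame | str | Path,
    constants: ModelConstants | None = None,
    *,
    target_max_oef: float = 0.6,
    calibration_roi: str = "NAWM",
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Calibrate in NAWM, estimate model OEF everywhere, compare with PET.

    ``roi_table`` is a DataFrame or CSV path with columns ``subject_id,
    roi, mtt_s, cth_s`` and, for calibration/agreement, ``pet_oef``.
    Without a ``pet_oef`` column the pipeline runs in estimation-only
    mode using the constants' own PtO2 and k.  When ``out_dir`` is given,
    writes ``calibration.json``, ``oef_table.csv`` and
    ``agreement_<roi>.json``.
    """
    constants = constants or ModelConstants()
    if not isinstance(roi_table, pd.DataFrame):
        roi_table = pd.read_csv(roi_table, float_precision="round_trip")
    missing = REQUIRED_COLUMNS - set(roi_table.columns)
    if missing:
        raise KeyError(f"input table is missing columns: {sorted(missing)}")

    calibration: CalibrationResult | None = None
    if "pet_oef" in roi_table.columns and roi_table["pet_oef"].notna().any():
        calibration = calibrate_cohort(
            roi_table, target_max_oef, constants, roi=calibration_roi
        )
        consts = constants.with_(PtO2=calibration.pto2, k=calibration.k_mean)
        logger.info(
            "calibrated PtO2 = %.2f mmHg, cohort mean k = %.1f 1/s (n = %d)",
            calibration.pto2,
            calibration.k_mean,
            calibration.n_converged,
        )
    else:
        consts = constants
        logger.info(
            "no pet_oef column: estimation-only mode with PtO2 = %.2f, k = %.1f",
            consts.PtO2,
            consts.k,
        )

    table = add_model_oef(roi_table, consts)

    reports: dict[str, AgreementReport] = {}
    if calibration is not None:
        for roi_name, group in table.groupby("roi", sort=False):
            ok = group["pet_oef"].notna()
            if ok.sum() >= 3:
                reports[str(roi_name)] = agreement(
                    group.loc[ok, "oef_mri"], group.loc[ok, "pet_oef"]
                )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "oef_table.csv", index=False)
        if calibration is not None:
            calibration.to_json(out_dir / "calibration.json")
        for roi_name, report in reports.items():
            payload = report.to_dict() | {
                "roi": roi_name,
                "difference_orientation": "mri_minus_pet",
                "constants": consts.to_file_dict(),
            }
            (out_dir / f"agreement_{roi_name}.json").write_text(
                json.dumps(payload, indent=2)
            )

    return PipelineResult(calibration=calibration, table=table, agreement=reports)
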