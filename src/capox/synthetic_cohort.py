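"""Seeded synthetic cohorts with the statistical structure of the study data.

Per-subject hemodynamics (MTT, CTH per ROI) are drawn from lognormal
distributions matched to published cohort means and ranges (range treated
as the central 95% interval), with a configurable within-subject
correlation between MTT and CTH.  Each subject carries a hidden true
oxygen-transfer rate constant k, drawn lognormally around a median of
68 1/s and truncated to the observed 22-175 1/s span.  "PET-observed"
OEF is the forward model OEF(MTT, CTH; k_true, PtO2) degraded by
multiplicative Gaussian noise (default CV 10%, the reported day-to-day
reproducibility of PET OEF) and clipped below the model's extraction
ceiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .oxygen_transport import ModelConstants, limit_extraction
from .transit_distribution import HemodynamicSummary, oef
from .calibration import calibrate_pto2

logger = logging.getLogger("capox")

__all__ = ["RoiTargets", "CohortConfig", "generate_cohort", "forward_pet"]


@dataclass(frozen=True)
class RoiTargets:
    """Cohort mean and (lo, hi) range for MTT and CTH in one ROI (s)."""

    mtt_mean: float
    mtt_range: tuple[float, float]
    cth_mean: float
    cth_range: tuple[float, float]

    def __post_init__(self) -> None:
        for mean, (lo, hi) in (
            (self.mtt_mean, self.mtt_range),
            (self.cth_mean, self.cth_range),
        ):
            if not 0 < lo <= mean <= hi:
                raise ValueError(
                    f"range ({lo}, {hi}) must be positive, ordered and bracket "
                    f"the mean {mean}"
                )


def _default_rois() -> dict[str, RoiTargets]:
    # Published cohort summaries: NAWM and gray matter.
    return {
        "NAWM": RoiTargets(4.52, (3.14, 6.42), 5.45, (3.82, 8.31)),
        "GM": RoiTargets(3.40, (2.35, 4.60), 4.08, (2.85, 6.07)),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults emulate the study cohort."""

    n_subjects: int = 68
    seed: int = 0
    rois: dict[str, RoiTargets] = field(default_factory=_default_rois)
    k_median: float = 68.0
    k_range: tuple[float, float] = (22.0, 175.0)
    #: set to 0 for a degenerate cohort with k_true == k_median everywhere
    k_sigma: float | None = None
    noise_cv: float = 0.10
    mtt_cth_corr: float = 0.8
    #: extraction ceiling defining the cohort's tissue oxygen tension; the
    #: generator forward-models at PtO2 = calibrate_pto2(target_max_oef) so
    #: that generation and calibration share one parameterization
    target_max_oef: float = 0.6

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        lo, hi = self.k_range
        if not 0 < lo <= self.k_median <= hi:
            raise ValueError("k_range must be positive, ordered and bracket k_median")
        if not -1 < self.mtt_cth_corr < 1:
            raise ValueError("mtt_cth_corr must be in (-1, 1)")

    @property
    def k_log_sigma(self) -> float:
        if self.k_sigma is not None:
            return self.k_sigma
        lo, hi = self.k_range
        return float(np.log(hi / lo) / (2 * 1.959964))


def _lognormal_params(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean whose central 95%
    interval has the width ratio hi/lo."""
    sigma = np.log(hi / lo) / (2 * 1.959964)
    mu = np.log(mean) - sigma**2 / 2.0
    return mu, sigma


def generate_cohort(
    config: CohortConfig, *, constants: ModelConstants | None = None
) -> pd.DataFrame:
    """Draw a cohort table (long format: one row per subject and ROI).

    Columns: ``subject_id, roi, mtt_s, cth_s, k_true, pet_oef``.  The
    same subject-level standard-normal draws parameterize every ROI, so
    hemodynamics are consistent within subject across ROIs.  Fully
    deterministic for a fixed config (PCG64 generator seeded with
    ``config.seed``).
    """
    constants = constants or ModelConstants()
    constants = constants.with_(PtO2=calibrate_pto2(config.target_max_oef, constants))
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    cols = ["subject_id", "roi", "mtt_s", "cth_s", "k_true", "pet_oef"]
    if n == 0:
        return pd.DataFrame(columns=cols)

    corr = config.mtt_cth_corr
    cov = np.array([[1.0, corr], [corr, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")

    sig = config.k_log_sigma
    if sig == 0:
        k_true = np.full(n, config.k_median)
    else:
        k_true = np.exp(np.log(config.k_median) + sig * rng.standard_normal(n))
        n_clip = np.count_nonzero((k_true < config.k_range[0]) | (k_true > config.k_range[1]))
        if n_clip:
            logger.info("generate_cohort: %d k_true values truncated to range", n_clip)
        k_true = np.clip(k_true, *config.k_range)

    rows = []
    for roi_name, targets in config.rois.items():
        mu_m, s_m = _lognormal_params(targets.mtt_mean, *targets.mtt_range)
        mu_c, s_c = _lognormal_params(targets.cth_mean, *targets.cth_range)
        mtt = np.clip(np.exp(mu_m + s_m * z[:, 0]), *targets.mtt_range)
        cth = np.clip(np.exp(mu_c + s_c * z[:, 1]), *targets.cth_range)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
                    "roi": roi_name,
                    "mtt_s": mtt,
                    "cth_s": cth,
                    "k_true": k_true,
                }
            )
        )
    cohort = pd.concat(rows, ignore_index=True)
    return forward_pet(cohort, constants, cv=config.noise_cv, rng=rng)


def forward_pet(
    cohort: pd.DataFrame,
    constants: ModelConstants,
    *,
    cv: float,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Attach a noisy ``pet_oef`` column via the forward oxygen model.

    ``pet_oef = OEF(mtt, cth; k_true, PtO2) * (1 + cv * z)`` with
    standard-normal ``z``, clipped into (0, extraction ceiling).  With
    ``cv = 0`` the observation equals the model OEF exactly.
    """
    if "k_true" not in cohort.columns:
        raise KeyError("cohort table needs a k_true column for the forward model")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    model = np.array(
        [
            oef(HemodynamicSummary(row.mtt_s, row.cth_s), constants.with_(k=row.k_true))
            for row in cohort.itertuples(index=False)
        ]
    )
    if cv == 0:
        observed = model
    else:
        observed = model * (1.0 + cv * rng.standard_normal(len(model)))
    ceiling = limit_extraction(constants.PtO2, constants)
    eps = 1e-9
    n_clip = int(np.count_nonzero((observed <= 0) | (observed >= ceiling)))
    if n_clip:
        logger.info("forward_pet: %d observations clipped into (0, ceiling)", n_clip)
    out = cohort.copy()
    out["pet_oef"] = np.clip(observed, eps, ceiling - eps)
    return out
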