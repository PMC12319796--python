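"""PET-side oxygen quantification: OEF = K1(O2)/CBF and a minimal 1TCM.

During an [15O]O2 scan the unidirectional clearance of labeled oxygen is
K1(O2) = CBF * OEF, so with CBF from an [15O]H2O scan the extraction
fraction is the ratio K1(O2)/CBF and the oxygen consumption rate is
CMRO2 = K1(O2) * [O2]a.  Water is not fully extracted during a single
capillary pass, which biases the H2O-PET CBF low by a factor E ~ 0.84;
measured CBF is divided by E before use.

A small single-tissue-compartment (1TCM) simulator and least-squares
fitter are included so the PET arm can be exercised end to end on
synthetic time-activity curves; it has two parameters (K1, k2), no
blood-volume term and no delay/dispersion handling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger("capox")

__all__ = [
    "WATER_EXTRACTION_E",
    "TacFrameSchedule",
    "PetObservation",
    "correct_cbf",
    "pet_oef",
    "cmro2",
    "gamma_variate_aif",
    "simulate_tac",
    "fit_1tcm",
    "FitResult",
    "add_pet_oef",
]

#: Fraction of complete blood/tissue water equilibration reached by
#: [15O]H2O during one capillary pass; H2O-PET CBF is divided by this.
WATER_EXTRACTION_E = 0.84


@dataclass(frozen=True)
class TacFrameSchedule:
    """Ordered PET frame durations in seconds."""

    durations: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.durations or any(d <= 0 for d in self.durations):
            raise ValueError("frame durations must be a non-empty positive sequence")

    @classmethod
    def default(cls) -> "TacFrameSchedule":
        """Standard 3-minute dynamic schedule: 12 x 5 s, 6 x 10 s, 3 x 20 s."""
        return cls(tuple([5.0] * 12 + [10.0] * 6 + [20.0] * 3))

    @property
    def n_frames(self) -> int:
        return len(self.durations)

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.durations)])

    @property
    def midpoints(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def total(self) -> float:
        return float(np.sum(self.durations))


@dataclass(frozen=True)
class PetObservation:
    """One subject's PET quantities (units must match between k1_o2 and cbf)."""

    k1_o2: float
    cbf_raw: float
    o2_a: float = float("nan")
    E: float = WATER_EXTRACTION_E

    def __post_init__(self) -> None:
        if self.k1_o2 < 0 or self.cbf_raw < 0:
            raise ValueError("k1_o2 and cbf_raw must be >= 0")
        if not 0 < self.E <= 1:
            raise ValueError(f"water extraction E must be in (0, 1], got {self.E}")

    @property
    def cbf(self) -> float:
        return correct_cbf(self.cbf_raw, self.E)

    @property
    def oef(self) -> float:
        return pet_oef(self.k1_o2, self.cbf)


def correct_cbf(cbf_raw, E: float = WATER_EXTRACTION_E):
    """Correct H2O-PET CBF for incomplete water extraction: CBF = raw / E."""
    if not 0 < E <= 1:
        raise ValueError(f"E must be in (0, 1], got {E}")
    cbf_raw = np.asarray(cbf_raw, dtype=float)
    if np.any(cbf_raw < 0):
        raise ValueError("cbf_raw must be >= 0")
    out = cbf_raw / E
    return out if out.ndim else float(out)


def pet_oef(k1_o2, cbf_corrected):
    """OEF as the ratio of oxygen clearance to (corrected) blood flow.

    Values above 1 are physically impossible and are flagged with a
    warning, not clipped.
    """
    k1_o2 = np.asarray(k1_o2, dtype=float)
    cbf = np.asarray(cbf_corrected, dtype=float)
    if np.any(cbf <= 0):
        raise ValueError("corrected CBF must be > 0")
    if np.any(k1_o2 < 0):
        raise ValueError("k1_o2 must be >= 0")
    out = k1_o2 / cbf
    if np.any(out > 1):
        warnings.warn("PET OEF > 1 encountered (K1(O2) exceeds CBF)", stacklevel=2)
    return out if out.ndim else float(out)


def cmro2(k1_o2, o2_a):
    """Oxygen consumption rate: CMRO2 = K1(O2) * [O2]a = CBF * OEF * [O2]a."""
    k1_o2 = np.asarray(k1_o2, dtype=float)
    o2_a = np.asarray(o2_a, dtype=float)
    if np.any(k1_o2 < 0) or np.any(o2_a < 0):
        raise ValueError("inputs must be >= 0")
    out = k1_o2 * o2_a
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# 1TCM simulation and fitting
# ---------------------------------------------------------------------------

def gamma_variate_aif(
    t,
    *,
    amplitude: float = 1.0,
    t0: float = 5.0,
    shape: float = 3.0,
    scale: float = 4.0,
):
    """Gamma-variate arterial bolus A * ((t-t0)/s)^r * exp(-(t-t0)/s), zero
    before arrival time ``t0``."""
    t = np.asarray(t, dtype=float)
    dt = np.maximum(t - t0, 0.0)
    out = amplitude * (dt / scale) ** shape * np.exp(-dt / scale)
    return out if out.ndim else float(out)


def _tissue_curve(K1: float, k2: float, t: np.ndarray, aif: np.ndarray) -> np.ndarray:
    """Solve dCt/dt = K1*aif - k2*Ct on the grid, with aif piecewise linear.

    Exact exponential update per step, so accuracy is limited only by the
    linear-in-step AIF approximation.
    """
    ct = np.zeros_like(t)
    dt = np.diff(t)
    if k2 == 0.0:
        ct[1:] = K1 * np.cumsum(0.5 * dt * (aif[1:] + aif[:-1]))
        return ct
    e = np.exp(-k2 * dt)
    # integral of exp(-k2(dt-u)) * (a0 + (a1-a0) u/dt) du over [0, dt]
    w0 = (1.0 - e) / k2
    w1 = (dt - w0) / (k2 * dt)
    for i in range(len(dt)):
        conv = aif[i] * w0[i] + (aif[i + 1] - aif[i]) * w1[i]
        ct[i + 1] = ct[i] * e[i] + K1 * conv
    return ct


def _frame_average(t: np.ndarray, curve: np.ndarray, schedule: TacFrameSchedule):
    edges = schedule.edges
    out = np.empty(schedule.n_frames)
    for i in range(schedule.n_frames):
        lo, hi = edges[i], edges[i + 1]
        sel = (t >= lo) & (t <= hi)
        tt = t[sel]
        if tt.size < 2:
            raise ValueError("AIF grid too coarse for the frame schedule")
        out[i] = np.trapezoid(curve[sel], tt) / (tt[-1] - tt[0])
    return out


def simulate_tac(
    K1: float,
    k2: float,
    aif_t: np.ndarray,
    aif: np.ndarray,
    schedule: TacFrameSchedule,
) -> np.ndarray:
    """Frame-averaged tissue activity for a single-tissue-compartment model.

    ``tissue(t) = K1 * (aif convolved with exp(-k2 t))``, averaged within
    each frame of ``schedule``.  The AIF must be sampled on a fine grid
    covering the schedule.
    """
    if K1 < 0 or k2 < 0:
        raise ValueError("K1 and k2 must be >= 0")
    aif_t = np.asarray(aif_t, dtype=float)
    aif = np.asarray(aif, dtype=float)
    if aif_t.shape != aif.shape or aif_t.ndim != 1:
        raise ValueError("aif_t and aif must be congruent 1-D arrays")
    if np.any(aif < 0):
        raise ValueError("AIF must be nonnegative")
    if aif_t[0] > 0 or aif_t[-1] < schedule.total:
        raise ValueError(
            f"AIF grid [{aif_t[0]}, {aif_t[-1]}] s does not cover the "
            f"schedule [0, {schedule.total}] s"
        )
    curve = _tissue_curve(K1, k2, aif_t, aif)
    return _frame_average(aif_t, curve, schedule)


@dataclass
class FitResult:
    K1: float
    k2: float
    converged: bool
    cost: float
    message: str = ""


def fit_1tcm(
    tac: np.ndarray,
    aif_t: np.ndarray,
    aif: np.ndarray,
    schedule: TacFrameSchedule,
) -> FitResult:
    """Least-squares (K1, k2) fit of a frame-averaged 1TCM to a TAC."""
    tac = np.asarray(tac, dtype=float)
    if tac.shape != (schedule.n_frames,):
        raise ValueError(
            f"TAC has {tac.shape} values for a {schedule.n_frames}-frame schedule"
        )
    if np.allclose(tac, 0.0):
        return FitResult(K1=0.0, k2=0.0, converged=True, cost=0.0, message="zero TAC")

    # crude initial guess: late-frame ratio to integrated AIF
    integ = np.trapezoid(aif, aif_t)
    k1_0 = max(float(np.max(tac)) / max(integ, 1e-12), 1e-6)

    def residuals(params):
        K1, k2 = params
        return simulate_tac(K1, k2, aif_t, aif, schedule) - tac

    fit = least_squares(
        residuals,
        x0=[k1_0, 0.01],
        bounds=([0.0, 0.0], [np.inf, 10.0]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not fit.success:
        logger.warning("1TCM fit did not converge: %s", fit.message)
    return FitResult(
        K1=float(fit.x[0]),
        k2=float(fit.x[1]),
        converged=bool(fit.success),
        cost=float(fit.cost),
        message=fit.message,
    )


# ---------------------------------------------------------------------------
# Table interface
# ---------------------------------------------------------------------------

def add_pet_oef(
    table: pd.DataFrame,
    *,
    E: float = WATER_EXTRACTION_E,
    k1_col: str = "k1_o2",
    cbf_col: str = "cbf_raw",
    o2a_col: str = "o2_a",
) -> pd.DataFrame:
    """Append cbf_corrected, oef_pet (and cmro2 when [O2]a is present)."""
    missing = {k1_col, cbf_col} - set(table.columns)
    if missing:
        raise KeyError(f"table is missing required columns: {sorted(missing)}")
    out = table.copy()
    out["cbf_corrected"] = correct_cbf(table[cbf_col].to_numpy(), E)
    out["oef_pet"] = pet_oef(table[k1_col].to_numpy(), out["cbf_corrected"].to_numpy())
    if o2a_col in table.columns:
        out["cmro2"] = cmro2(table[k1_col].to_numpy(), table[o2a_col].to_numpy())
    return out
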