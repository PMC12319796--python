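"""Hemoglobin oxygen binding and single-capillary oxygen extraction.

The model describes oxygen leaving a capillary of normalized length
``x in [0, 1]`` during a transit of duration ``tau`` (s).  Total blood
oxygen concentration ``C`` (hemoglobin-bound, mL O2 per mL blood) obeys

    dC/dx = -k * tau * alpha_H * (P(C) - PtO2),

where ``P(C) = P50 * (C / (B - C))**(1/h)`` is the inverse Hill relation
giving the plasma oxygen tension in equilibrium with the bound pool,
``PtO2`` is the (constant) tissue oxygen tension acting as the sink, and
``k`` (1/s) is the rate constant of transcapillary oxygen transfer.  The
single-capillary extraction fraction is ``Q(tau) = 1 - C(1) / C(0)`` with
inflow concentration ``C(0) = S_a * B``.

``Q`` depends on ``k`` and ``tau`` only through their product, so the ODE
is solved once per parameter set on the stretched coordinate
``s = k * tau * x`` with a dense interpolant, and every subsequent
evaluation is an interpolant lookup.  Beyond ``s = S_MAX`` the solution is
within numerical noise of the equilibrium concentration ``B * S(PtO2)``
and is clamped there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.integrate import solve_ivp

logger = logging.getLogger("capox")

__all__ = [
    "ModelConstants",
    "NoGradientError",
    "DEFAULT_CONSTANTS",
    "hill_saturation",
    "plasma_tension",
    "limit_extraction",
    "single_capillary_extraction",
    "extraction_profile",
    "load_constants",
    "S_MAX",
]

#: Stretched-coordinate horizon: for s = k*tau above this the capillary
#: blood has equilibrated with tissue to well below 1e-8 in extraction.
S_MAX = 1.0e5

# Solver tolerances for the dense capillary profile.
_RTOL = 1e-10
_ATOL = 1e-14


class NoGradientError(ValueError):
    """Tissue oxygen tension at or above the inflow tension: no extraction."""


@dataclass(frozen=True)
class ModelConstants:
    """Physiological constants of the oxygen-binding/transport model.

    Parameters
    ----------
    alpha_H : float
        Henry's constant, oxygen solubility in plasma
        (mL O2 · mL⁻¹ · mmHg⁻¹).
    P50 : float
        Oxygen tension at half hemoglobin saturation (mmHg).
    B : float
        Maximum hemoglobin-bound oxygen concentration (mL O2 / mL blood).
    h : float
        Hill coefficient (dimensionless).
    S_a : float
        Arterial oxygen saturation fraction, in (0, 1].
    PtO2 : float
        Tissue oxygen tension (mmHg); one of the two calibratable
        parameters.
    k : float
        Transcapillary oxygen transfer rate constant (1/s); the other
        calibratable parameter.
    """

    alpha_H: float = 3.1e-5
    P50: float = 26.0
    B: float = 0.1943
    h: float = 2.8
    S_a: float = 0.95
    PtO2: float = 21.8
    k: float = 68.0

    def __post_init__(self) -> None:
        for name in ("alpha_H", "P50", "B", "h", "k"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.S_a <= 1:
            raise ValueError(f"S_a must be in (0, 1], got {self.S_a}")
        if self.PtO2 < 0:
            raise ValueError(f"PtO2 must be >= 0, got {self.PtO2}")

    # -- derived quantities -------------------------------------------------

    @property
    def c_arterial(self) -> float:
        """Inflow bound-oxygen concentration C(0) = S_a * B."""
        return self.S_a * self.B

    @property
    def c_equilibrium(self) -> float:
        """Bound concentration in equilibrium with tissue tension."""
        return self.B * float(hill_saturation(self.PtO2, self))

    @property
    def has_gradient(self) -> bool:
        """Whether the inflow blood can lose oxygen to tissue at all."""
        return self.c_equilibrium < self.c_arterial

    def with_(self, **kwargs: float) -> "ModelConstants":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    # -- (de)serialization --------------------------------------------------

    _FILE_KEYS = {
        "alpha_H": "alpha_H",
        "P50_mmHg": "P50",
        "B": "B",
        "hill_h": "h",
        "S_a": "S_a",
        "PtO2_mmHg": "PtO2",
        "k_per_s": "k",
    }

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ModelConstants":
        kwargs = {}
        for key, value in mapping.items():
            if key in cls._FILE_KEYS:
                kwargs[cls._FILE_KEYS[key]] = float(value)
            elif key in cls.__dataclass_fields__:
                kwargs[key] = float(value)
            else:
                raise KeyError(f"unknown model-constant key: {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConstants":
        """Load constants from a YAML or JSON config file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValueError(f"config {path} did not parse to a mapping")
        return cls.from_mapping(data)

    def to_file_dict(self) -> dict[str, float]:
        inv = {v: k for k, v in self._FILE_KEYS.items()}
        return {inv[name]: value for name, value in asdict(self).items()}


def load_constants(path: str | Path | None = None) -> ModelConstants:
    """Constants from a config file, or the package defaults."""
    if path is None:
        return DEFAULT_CONSTANTS
    return ModelConstants.from_file(path)


# ---------------------------------------------------------------------------
# Hill equation and its inverse
# ---------------------------------------------------------------------------

def hill_saturation(P, constants: ModelConstants):
    """Hemoglobin oxygen saturation S(P) = P^h / (P^h + P50^h).

    Accepts scalars or arrays; negative tensions are a domain error.
    S(0) = 0, S(P50) = 1/2, strictly increasing, bounded by 1.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("oxygen tension must be >= 0")
    ratio = (P / constants.P50) ** constants.h
    out = ratio / (1.0 + ratio)
    return out if out.ndim else float(out)


def plasma_tension(C, constants: ModelConstants):
    """Inverse Hill: tension P such that B * S(P) = C.

    ``P = P50 * (C / (B - C))**(1/h)``; the plasma oxygen concentration in
    equilibrium with the bound pool is then ``alpha_H * P``.
    Domain: 0 <= C < B (the inverse diverges at full saturation).
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0) or np.any(C >= constants.B):
        raise ValueError(f"bound concentration must be in [0, B={constants.B})")
    P = constants.P50 * (C / (constants.B - C)) ** (1.0 / constants.h)
    return P if P.ndim else float(P)


def limit_extraction(PtO2, constants: ModelConstants, *, on_no_gradient: str = "zero"):
    """Maximum extraction fraction in the fast-exchange (k -> inf) limit.

    When transfer is instantaneous the outflow blood is in equilibrium
    with tissue, so the ceiling is ``1 - S(PtO2) / S_a`` independent of
    the transit-time distribution.

    Parameters
    ----------
    PtO2 : float or array
        Tissue oxygen tension (mmHg).
    on_no_gradient : {"zero", "raise"}
        Behaviour when S(PtO2) >= S_a (tissue tension at or above the
        arterial-equivalent tension): return 0, or raise
        :class:`NoGradientError`.
    """
    sat = hill_saturation(PtO2, constants)
    out = 1.0 - np.asarray(sat) / constants.S_a
    if np.any(out <= 0):
        if on_no_gradient == "raise":
            raise NoGradientError(
                f"PtO2={PtO2} gives saturation >= arterial S_a={constants.S_a}"
            )
        out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Capillary extraction ODE
# ---------------------------------------------------------------------------

class ExtractionProfile:
    """Dense solution of the capillary ODE on the coordinate s = k*tau.

    Callable: ``profile(s)`` returns the extraction fraction
    ``Q = 1 - C(s)/C(0)`` for scalar or array ``s >= 0``.
    """

    def __init__(self, constants: ModelConstants):
        if not constants.has_gradient:
            raise NoGradientError(
                "tissue tension at/above inflow tension: extraction impossible "
                f"(C_eq={constants.c_equilibrium:.4g} >= C0={constants.c_arterial:.4g})"
            )
        self.constants = constants
        c0 = constants.c_arterial
        ceq = constants.c_equilibrium
        B, aH, P50, h, pt = (
            constants.B,
            constants.alpha_H,
            constants.P50,
            constants.h,
            constants.PtO2,
        )
        ceiling = B * (1.0 - 1e-12)

        def rhs(s, C):
            Cc = np.clip(C, ceq, ceiling)  # exact solution never leaves [ceq, c0]
            return -aH * (P50 * (Cc / (B - Cc)) ** (1.0 / h) - pt)

        sol = solve_ivp(
            rhs,
            (0.0, S_MAX),
            [c0],
            method="Radau",
            rtol=_RTOL,
            atol=_ATOL,
            dense_output=True,
        )
        if not sol.success:  # pragma: no cover - solver failure is fatal
            raise RuntimeError(f"capillary ODE solve failed: {sol.message}")
        self._sol = sol
        self._c0 = c0
        self._q_limit = 1.0 - ceq / c0

    @property
    def q_limit(self) -> float:
        """Extraction ceiling approached as k*tau -> infinity."""
        return self._q_limit

    def __call__(self, s):
        s = np.asarray(s, dtype=float)
        if np.any(s < 0):
            raise ValueError("k*tau must be >= 0")
        scalar = s.ndim == 0
        c = self._sol.sol(np.minimum(np.atleast_1d(s), S_MAX))[0]
        # guard interpolation wiggle outside the physical band
        c = np.clip(c, self.constants.c_equilibrium, self._c0)
        q = 1.0 - c / self._c0
        return float(q[0]) if scalar else q.reshape(s.shape)


_PROFILE_CACHE: dict[tuple, ExtractionProfile] = {}


def extraction_profile(constants: ModelConstants) -> ExtractionProfile:
    """Cached dense extraction profile for the given constants.

    ``k`` is deliberately absent from the cache key: the profile is a
    function of s = k*tau, so one solve serves every k.
    """
    key = (
        constants.alpha_H,
        constants.P50,
        constants.B,
        constants.h,
        constants.S_a,
        constants.PtO2,
    )
    profile = _PROFILE_CACHE.get(key)
    if profile is None:
        profile = ExtractionProfile(constants)
        if len(_PROFILE_CACHE) > 64:
            _PROFILE_CACHE.clear()
        _PROFILE_CACHE[key] = profile
    return profile


def single_capillary_extraction(tau, constants: ModelConstants):
    """Extraction fraction Q(tau) of one capillary with transit time tau (s).

    Scalar or array ``tau``; uses the rate constant ``constants.k``.
    Q(0) = 0 and Q increases monotonically toward
    :func:`limit_extraction` as k*tau grows.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("transit time must be >= 0")
    profile = extraction_profile(constants)
    return profile(constants.k * tau)


# ---------------------------------------------------------------------------
# Default constants, pinned by two published operating points
# ---------------------------------------------------------------------------

def _validate_defaults(constants: ModelConstants) -> None:
    """The adopted Hill constants must reproduce two known extraction
    ceilings: 0.60 at PtO2 = 21.8 mmHg and 0.50 at 25 mmHg."""
    for pto2, target in ((21.8, 0.60), (25.0, 0.50)):
        got = limit_extraction(pto2, constants)
        if abs(got - target) > 0.01:
            raise AssertionError(
                f"default constants fail ceiling anchor: limit({pto2}) = "
                f"{got:.4f}, expected {target} +- 0.01"
            )


DEFAULT_CONSTANTS = ModelConstants()
_validate_defaults(DEFAULT_CONSTANTS)
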