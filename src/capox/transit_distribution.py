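"""Gamma transit-time distribution and the tissue-level OEF integral.

Capillary transit times in a voxel or ROI are modeled as gamma-distributed,
``h(tau; alpha, beta)``, parameterized from the two measurable moments:
mean transit time MTT = alpha*beta and capillary transit time heterogeneity
CTH = sqrt(alpha)*beta (the standard deviation of transit times).  Tissue
oxygen extraction is the expectation of the single-capillary extraction
over that distribution:

    OEF = integral_0^inf h(tau) * Q(tau) dtau.

The integral is evaluated by Gauss-Legendre quadrature on the gamma
support truncated at the 1 - 1e-7 quantile.  White-matter hemodynamics
typically imply shape alpha < 1 (CTH > MTT), where the density has an
integrable singularity at tau = 0; the substitution u = (tau/beta)**alpha
removes it, leaving a smooth integrand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import gamma as gamma_dist

from .oxygen_transport import ModelConstants, extraction_profile

logger = logging.getLogger("capox")

__all__ = [
    "TransitTimeDistribution",
    "HemodynamicSummary",
    "gamma_from_moments",
    "gamma_pdf",
    "oef",
    "oef_map",
    "OefLookup",
    "add_model_oef",
    "oef_nifti",
]

#: Upper-tail probability at which the OEF integral is truncated.
TAIL_PROB = 1e-7
#: Default number of Gauss-Legendre nodes.
N_NODES = 256


@dataclass(frozen=True)
class HemodynamicSummary:
    """Per-region transit-time moments: MTT (mean, s) and CTH (std, s)."""

    mtt: float
    cth: float

    def __post_init__(self) -> None:
        if not self.mtt > 0:
            raise ValueError(f"mtt must be > 0, got {self.mtt}")
        if self.cth < 0:
            raise ValueError(f"cth must be >= 0, got {self.cth}")


@dataclass(frozen=True)
class TransitTimeDistribution:
    """Gamma transit-time density with shape ``alpha`` and scale ``beta`` (s)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be > 0")

    @property
    def mean(self) -> float:
        return self.alpha * self.beta

    @property
    def std(self) -> float:
        return np.sqrt(self.alpha) * self.beta

    def quantile(self, p: float) -> float:
        return float(gamma_dist.ppf(p, self.alpha, scale=self.beta))


def gamma_from_moments(summary: HemodynamicSummary) -> TransitTimeDistribution:
    """Invert (MTT, CTH) to gamma (alpha, beta).

    alpha = (MTT/CTH)^2, beta = CTH^2/MTT.  CTH = 0 is a degenerate
    (delta) distribution and is rejected here; :func:`oef` short-circuits
    that case before calling this.
    """
    if summary.cth == 0:
        raise ValueError("cth = 0 is a degenerate (delta) distribution")
    alpha = (summary.mtt / summary.cth) ** 2
    beta = summary.cth**2 / summary.mtt
    return TransitTimeDistribution(alpha=alpha, beta=beta)


def gamma_pdf(tau, dist: TransitTimeDistribution):
    """Density h(tau; alpha, beta) of the transit-time distribution (1/s)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("transit time must be >= 0")
    out = gamma_dist.pdf(tau, dist.alpha, scale=dist.beta)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# OEF integral
# ---------------------------------------------------------------------------

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GL_CACHE:
        _GL_CACHE[n] = special.roots_legendre(n)
    return _GL_CACHE[n]


def _quadrature_points(dist: TransitTimeDistribution, n_nodes: int):
    """Transit times and weights such that OEF = sum(w * Q(tau)).

    The gamma density is folded into the weights.  For alpha < 1 the
    substitution u = (tau/beta)**alpha regularizes the tau -> 0
    singularity; the transformed integrand is exp(-u^(1/alpha))/Gamma(alpha+1)
    which is smooth on [0, u_max].
    """
    a, b = dist.alpha, dist.beta
    q = dist.quantile(1.0 - TAIL_PROB)
    x, w = _gl_nodes(n_nodes)
    if a < 1.0:
        u_max = (q / b) ** a
        u = 0.5 * u_max * (x + 1.0)
        wu = 0.5 * u_max * w
        tau = b * u ** (1.0 / a)
        # h(tau) dtau = exp(-u**(1/a)) / Gamma(a+1) du
        weights = wu * np.exp(-(u ** (1.0 / a))) / special.gamma(a + 1.0)
    else:
        # two-sided truncation: for large alpha the density is a narrow
        # peak and nodes spread over [0, q] would not resolve it
        q_lo = dist.quantile(TAIL_PROB)
        half = 0.5 * (q - q_lo)
        tau = q_lo + half * (x + 1.0)
        weights = half * w * gamma_dist.pdf(tau, a, scale=b)
    return tau, weights


def oef(
    summary: HemodynamicSummary,
    constants: ModelConstants,
    *,
    n_nodes: int = N_NODES,
) -> float:
    """Tissue oxygen extraction fraction for given transit-time moments.

    Integrates the single-capillary extraction Q(tau) against the gamma
    transit-time density implied by (MTT, CTH), using the rate constant
    ``constants.k`` and tissue tension ``constants.PtO2``.  A CTH of zero
    collapses the distribution to a delta at MTT, i.e. Q(MTT) itself.
    """
    profile = extraction_profile(constants)  # raises NoGradientError early
    if summary.cth == 0:
        return profile(constants.k * summary.mtt)
    dist = gamma_from_moments(summary)
    tau, weights = _quadrature_points(dist, n_nodes)
    return float(np.sum(weights * profile(constants.k * tau)))


def oef_vector(mtt, cth, constants: ModelConstants, *, n_nodes: int = N_NODES):
    """Vectorized :func:`oef` over congruent 1-D arrays of MTT and CTH."""
    mtt = np.asarray(mtt, dtype=float)
    cth = np.asarray(cth, dtype=float)
    out = np.empty(mtt.shape, dtype=float)
    for i in np.ndindex(mtt.shape):
        out[i] = oef(HemodynamicSummary(mtt[i], cth[i]), constants, n_nodes=n_nodes)
    return out


# ---------------------------------------------------------------------------
# Map (voxelwise) evaluation
# ---------------------------------------------------------------------------

class OefLookup:
    """Bilinear OEF interpolator on a log-spaced (MTT, CTH) grid.

    Trades ~1e-4 absolute OEF accuracy for constant-time evaluation;
    intended for voxelwise maps.  Queries outside the grid fall back to
    exact evaluation.
    """

    def __init__(
        self,
        constants: ModelConstants,
        mtt_range: tuple[float, float] = (0.2, 60.0),
        cth_range: tuple[float, float] = (0.05, 60.0),
        n_grid: int = 96,
    ):
        self.constants = constants
        self.mtt_grid = np.geomspace(*mtt_range, n_grid)
        self.cth_grid = np.geomspace(*cth_range, n_grid)
        vals = np.empty((n_grid, n_grid))
        for i, m in enumerate(self.mtt_grid):
            vals[i] = oef_vector(np.full(n_grid, m), self.cth_grid, constants)
        self._vals = vals

    def __call__(self, mtt, cth):
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (np.log(self.mtt_grid), np.log(self.cth_grid)),
            self._vals,
            bounds_error=False,
            fill_value=np.nan,
        )
        mtt = np.asarray(mtt, dtype=float)
        cth = np.asarray(cth, dtype=float)
        pts = np.column_stack([np.log(mtt).ravel(), np.log(cth).ravel()])
        out = interp(pts).reshape(mtt.shape)
        miss = ~np.isfinite(out) & np.isfinite(mtt) & np.isfinite(cth)
        if np.any(miss):  # out-of-grid voxels: exact evaluation
            out[miss] = oef_vector(mtt[miss], cth[miss], self.constants)
        return out


def oef_map(
    mtt_map: np.ndarray,
    cth_map: np.ndarray,
    constants: ModelConstants,
    mask: np.ndarray | None = None,
    *,
    lookup: OefLookup | bool = False,
) -> np.ndarray:
    """Voxelwise OEF from MTT and CTH maps (any congruent array shape).

    Voxels outside ``mask`` or with non-finite/invalid inputs yield NaN
    (invalid in-mask voxels are counted in the log).  With
    ``lookup=True`` (or an :class:`OefLookup` instance) evaluation goes
    through the interpolation grid instead of per-voxel quadrature.
    """
    mtt_map = np.asarray(mtt_map, dtype=float)
    cth_map = np.asarray(cth_map, dtype=float)
    if mtt_map.shape != cth_map.shape:
        raise ValueError(
            f"shape mismatch: mtt {mtt_map.shape} vs cth {cth_map.shape}"
        )
    if mask is None:
        mask = np.ones(mtt_map.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != mtt_map.shape:
            raise ValueError(f"mask shape {mask.shape} != map shape {mtt_map.shape}")

    valid = mask & np.isfinite(mtt_map) & np.isfinite(cth_map)
    valid &= (mtt_map > 0) & (cth_map >= 0)
    n_bad = int(np.count_nonzero(mask & ~valid))
    if n_bad:
        logger.warning("oef_map: %d in-mask voxels with invalid inputs -> NaN", n_bad)

    out = np.full(mtt_map.shape, np.nan)
    if not np.any(valid):
        return out
    if lookup:
        if lookup is True:
            lookup = OefLookup(constants)
        out[valid] = lookup(mtt_map[valid], cth_map[valid])
    else:
        out[valid] = oef_vector(mtt_map[valid], cth_map[valid], constants)
    return out


def oef_nifti(
    mtt_path,
    cth_path,
    out_path,
    constants: ModelConstants,
    mask_path=None,
    *,
    lookup: bool = True,
):
    """Voxelwise OEF between NIfTI files; affine/header pass through from
    the MTT image."""
    import nibabel as nib

    mtt_img = nib.load(str(mtt_path))
    cth_img = nib.load(str(cth_path))
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
    data = oef_map(
        np.asarray(mtt_img.get_fdata()),
        np.asarray(cth_img.get_fdata()),
        constants,
        mask,
        lookup=lookup,
    )
    out = nib.Nifti1Image(data.astype(np.float32), mtt_img.affine, mtt_img.header)
    out.header.set_data_dtype(np.float32)
    nib.save(out, str(out_path))
    return out


# ---------------------------------------------------------------------------
# Table interface
# ---------------------------------------------------------------------------

def add_model_oef(
    table: pd.DataFrame,
    constants: ModelConstants,
    *,
    mtt_col: str = "mtt_s",
    cth_col: str = "cth_s",
    out_col: str = "oef_mri",
) -> pd.DataFrame:
    """Append a model-OEF column to a per-subject/per-ROI table."""
    missing = {mtt_col, cth_col} - set(table.columns)
    if missing:
        raise KeyError(f"table is missing required columns: {sorted(missing)}")
    out = table.copy()
    out[out_col] = oef_vector(
        table[mtt_col].to_numpy(), table[cth_col].to_numpy(), constants
    )
    return out
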