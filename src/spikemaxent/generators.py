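"""Validation distributions: Gaussian-copula mixtures with Poisson marginals.

A copula couples fixed discrete marginals with a chosen dependence structure.
On a count grid the copula-based pmf is the rectangle inclusion–exclusion of
the copula CDF evaluated at the marginal CDF knots:

    P(i, j) = C(F1(i), F2(j)) - C(F1(i-1), F2(j)) - C(F1(i), F2(j-1))
              + C(F1(i-1), F2(j-1)),       F(-1) = 0.

Mixing two Gaussian copulas with opposite-sign parameters produces strong
higher-order dependence (a cross-shaped pmf) while the linear correlation can
be calibrated to any small target — the construction behind the two
benchmark families:

* ``M1`` — correlation 0 for both components (higher-order structure only);
* ``M2`` — correlation 0.2 for both components (higher-order structure in
  the presence of weak linear correlation).

The family pmf is the outer mixture (1 - m) · ME + m · copula table; the
mixture parameter m in [0, 1] dials the strength of the higher-order
correlations while marginals and correlation stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .errors import CalibrationError, InvalidParameterError
from .maxent import (
    MarginalSpec,
    MaxEntModel,
    TruncatedBivariatePMF,
    TruncatedSupport,
    fit_maxent,
    pearson_correlation,
    truncate_support,
)

__all__ = [
    "GaussianCopula",
    "MixtureCopula",
    "CopulaMixtureModel",
    "gaussian_copula_cdf",
    "copula_pmf",
    "calibrate_rho2",
    "build_mixture_model",
]

#: copula parameter of the first mixture component; large so the component
#: pair (rho1, calibrated rho2 < 0) carries pronounced higher-order structure
DEFAULT_RHO1 = 0.9
#: inner weight between the two Gaussian copulas
DEFAULT_COPULA_WEIGHT = 0.5
#: default Poisson rate: 30 Hz in 100 ms bins
DEFAULT_RATE = 3.0

_FAMILY_TARGETS = {"M1": 0.0, "M2": 0.2}


@dataclass(frozen=True)
class GaussianCopula:
    """Bivariate Gaussian copula C(u, v) = Phi2_rho(Phi^-1(u), Phi^-1(v))."""

    rho_c: float

    def __post_init__(self):
        if not -1.0 < self.rho_c < 1.0:
            raise InvalidParameterError("copula parameter must be in (-1, 1)")

    def cdf(self, u, v):
        return gaussian_copula_cdf(self, u, v)


@dataclass(frozen=True)
class MixtureCopula:
    """Convex combination of two Gaussian copulas (itself a valid copula)."""

    weight: float
    comp1: GaussianCopula
    comp2: GaussianCopula

    def __post_init__(self):
        if not 0.0 <= self.weight <= 1.0:
            raise InvalidParameterError("mixture weight must be in [0, 1]")

    def cdf(self, u, v):
        return (self.weight * self.comp1.cdf(u, v)
                + (1.0 - self.weight) * self.comp2.cdf(u, v))


def gaussian_copula_cdf(c: GaussianCopula, u, v):
    """Evaluate the Gaussian copula CDF elementwise on broadcastable arrays."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if (u < 0).any() or (u > 1).any() or (v < 0).any() or (v > 1).any():
        raise InvalidParameterError("copula arguments must lie in [0, 1]")
    u, v = np.broadcast_arrays(u, v)
    out = np.empty(u.shape)
    # boundary conventions: Phi^-1(0) = -inf, Phi^-1(1) = +inf
    zero = (u == 0) | (v == 0)
    u_one = u == 1
    v_one = v == 1
    interior = ~(zero | u_one | v_one)
    out[zero] = 0.0
    out[u_one] = v[u_one]
    out[v_one] = u[v_one]
    if interior.any():
        a = stats.norm.ppf(u[interior])
        b = stats.norm.ppf(v[interior])
        cov = np.array([[1.0, c.rho_c], [c.rho_c, 1.0]])
        bvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov,
                                        allow_singular=False)
        out[interior] = bvn.cdf(np.column_stack([a, b]))
    out[u_one & v_one] = 1.0
    return out if out.ndim else float(out)


def copula_pmf(cop: GaussianCopula | MixtureCopula, mx: MarginalSpec,
               my: MarginalSpec, support: TruncatedSupport
               ) -> TruncatedBivariatePMF:
    """Discrete pmf induced by a copula on Poisson marginals.

    Rectangle masses of the copula CDF over the marginal CDF grid; the
    result has exactly the truncated Poisson marginals after renormalization
    over the grid.
    """
    fx = np.concatenate([[0.0], mx.cdf(support.counts_x)])
    fy = np.concatenate([[0.0], my.cdf(support.counts_y)])
    fx = np.clip(fx, 0.0, 1.0)
    fy = np.clip(fy, 0.0, 1.0)
    grid = cop.cdf(fx[:, None], fy[None, :])
    probs = np.diff(np.diff(grid, axis=0), axis=1)
    if (probs < -1e-12).any():
        raise InvalidParameterError(
            f"copula produced negative rectangle mass {probs.min():.3e}")
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    return TruncatedBivariatePMF(support, probs, _validate=False)


def calibrate_rho2(rho1: float, weight: float, target_corr: float,
                   mx: MarginalSpec, my: MarginalSpec,
                   support: TruncatedSupport, tol: float = 1e-4) -> float:
    """Solve for the second copula parameter matching a target correlation.

    Bisection (Brent) on rho2 in (-1, 1) so that the Pearson correlation of
    the discrete mixture-copula table equals ``target_corr`` within ``tol``.
    """
    c1 = GaussianCopula(rho1)

    def gap(rho2: float) -> float:
        mix = MixtureCopula(weight, c1, GaussianCopula(rho2))
        return pearson_correlation(copula_pmf(mix, mx, my, support)) - target_corr

    lo, hi = -1.0 + 1e-6, 1.0 - 1e-6
    g_lo, g_hi = gap(lo), gap(hi)
    if abs(g_lo) <= 1e-12:
        return lo
    if abs(g_hi) <= 1e-12:
        return hi
    if g_lo * g_hi > 0:
        raise CalibrationError(
            f"target correlation {target_corr} not bracketed by rho2 in "
            f"({lo:.4f}, {hi:.4f}): gaps ({g_lo:.4f}, {g_hi:.4f})")
    rho2 = optimize.brentq(gap, lo, hi, xtol=min(tol * 1e-2, 1e-6))
    if abs(gap(rho2)) > tol:
        raise CalibrationError("calibration did not reach tolerance")
    return float(rho2)


@dataclass(frozen=True)
class CopulaMixtureModel:
    """Outer mixture (1 - m) · ME + m · copula table with matched constraints."""

    family: str
    m: float
    rate: float
    target_corr: float
    me_component: MaxEntModel
    copula_component: TruncatedBivariatePMF
    rho1: float
    rho2: float
    copula_weight: float

    @property
    def pmf(self) -> TruncatedBivariatePMF:
        probs = ((1.0 - self.m) * self.me_component.pmf.probs
                 + self.m * self.copula_component.probs)
        return TruncatedBivariatePMF(self.me_component.pmf.support, probs,
                                     _validate=False)

    def describe(self) -> dict:
        return {
            "family": self.family, "m": self.m, "rate": self.rate,
            "target_corr": self.target_corr, "rho1": self.rho1,
            "rho2": self.rho2, "copula_weight": self.copula_weight,
            "support": list(self.me_component.pmf.support.shape),
        }


@lru_cache(maxsize=32)
def _calibrated_components(family: str, rate: float, rho1: float,
                           copula_weight: float):
    """ME component, copula component and rho2 for a family at a rate."""
    target = _FAMILY_TARGETS[family]
    mx = my = MarginalSpec(rate)
    support = truncate_support(mx, my)
    me = fit_maxent(mx, my, target, support)
    rho2 = calibrate_rho2(rho1, copula_weight, target, mx, my, support)
    mix = MixtureCopula(copula_weight, GaussianCopula(rho1), GaussianCopula(rho2))
    cop = copula_pmf(mix, mx, my, support)
    return me, cop, rho2


def build_mixture_model(family: str, m: float, rate: float = DEFAULT_RATE,
                        rho1: float = DEFAULT_RHO1,
                        copula_weight: float = DEFAULT_COPULA_WEIGHT
                        ) -> CopulaMixtureModel:
    """Build an M1/M2 benchmark distribution with mixture parameter m.

    Both components are calibrated to the family's target correlation
    (0 for M1, 0.2 for M2), so correlation and marginals are independent of
    m; only the higher-order structure changes.
    """
    family = family.upper()
    if family not in _FAMILY_TARGETS:
        raise InvalidParameterError(f"family must be one of {sorted(_FAMILY_TARGETS)}")
    if not 0.0 <= m <= 1.0:
        raise InvalidParameterError("mixture parameter m must be in [0, 1]")
    if rate <= 0:
        raise InvalidParameterError("rate must be positive")
    me, cop, rho2 = _calibrated_components(family, float(rate), float(rho1),
                                           float(copula_weight))
    return CopulaMixtureModel(family, float(m), float(rate),
                              _FAMILY_TARGETS[family], me, cop,
                              float(rho1), float(rho2), float(copula_weight))
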