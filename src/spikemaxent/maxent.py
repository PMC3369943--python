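"""Bivariate maximum entropy distributions with fixed marginals and correlation.

The reference model of the test: among all distributions on a finite count
grid with the given (truncated, renormalized) Poisson marginals and a given
Pearson correlation coefficient, the entropy maximizer has the unique
exponential-family form

    P(X = i, Y = j)  ∝  a_i · b_j · exp(θ · i · j),

where the row/column factors ``a``, ``b`` enforce the marginal constraints and
the single interaction exponent ``θ`` tilts the product distribution until the
product moment E[XY] matches the requested correlation.  We solve for
``a, b`` at fixed ``θ`` by iterative proportional fitting (Sinkhorn scaling)
and for ``θ`` by a bracketed one-dimensional root solve on E[XY], which is
strictly increasing in ``θ``.

All entropies are in bits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp, xlogy

from .data import CountPairSample
from .errors import (
    ConvergenceError,
    DegenerateMarginalError,
    FeasibilityError,
    InvalidParameterError,
)

__all__ = [
    "TruncatedSupport",
    "MarginalSpec",
    "TruncatedBivariatePMF",
    "MaxEntModel",
    "FeasibleCorrelationRange",
    "truncate_support",
    "fit_maxent",
    "feasible_correlation_range",
    "entropy",
    "pearson_correlation",
    "sample",
]

#: truncated-away marginal mass allowed by default; counts this improbable
#: cannot influence p-values at the sample sizes the test is meant for.
DEFAULT_TRUNCATION_EPSILON = 1e-10
DEFAULT_CONSTRAINT_TOL = 1e-9
_MAX_ITER = 10_000


@dataclass(frozen=True)
class TruncatedSupport:
    """Finite count grid {0..max_count_x} × {0..max_count_y}."""

    max_count_x: int
    max_count_y: int

    def __post_init__(self):
        if self.max_count_x < 1 or self.max_count_y < 1:
            raise InvalidParameterError("support bounds must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.max_count_x + 1, self.max_count_y + 1)

    @property
    def size(self) -> int:
        return (self.max_count_x + 1) * (self.max_count_y + 1)

    @property
    def counts_x(self) -> np.ndarray:
        return np.arange(self.max_count_x + 1)

    @property
    def counts_y(self) -> np.ndarray:
        return np.arange(self.max_count_y + 1)

    def union(self, other: "TruncatedSupport") -> "TruncatedSupport":
        return TruncatedSupport(max(self.max_count_x, other.max_count_x),
                                max(self.max_count_y, other.max_count_y))


@dataclass(frozen=True)
class MarginalSpec:
    """Parametric single-neuron count distribution (Poisson only for now)."""

    rate: float
    family: str = "poisson"

    def __post_init__(self):
        if self.family != "poisson":
            raise InvalidParameterError(f"unsupported marginal family {self.family!r}")
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise InvalidParameterError("rate must be positive and finite")

    def pmf(self, bound: int) -> np.ndarray:
        """Truncated pmf on {0..bound}, renormalized to sum to one."""
        p = stats.poisson.pmf(np.arange(bound + 1), self.rate)
        total = p.sum()
        if total <= 0:
            raise InvalidParameterError("marginal mass vanished on the support")
        return p / total

    def cdf(self, k: np.ndarray | int) -> np.ndarray:
        return stats.poisson.cdf(k, self.rate)


class TruncatedBivariatePMF:
    """Probability table on a finite count grid — the universal currency.

    Wraps a nonnegative array summing to one, with cached moments.
    """

    __slots__ = ("support", "probs", "_flat_cdf")

    def __init__(self, support: TruncatedSupport, probs: np.ndarray,
                 *, _validate: bool = True):
        probs = np.asarray(probs, dtype=float)
        if probs.shape != support.shape:
            raise InvalidParameterError(
                f"probs shape {probs.shape} != support shape {support.shape}")
        if _validate:
            if (probs < -1e-12).any():
                raise InvalidParameterError("negative probability entries")
            probs = np.clip(probs, 0.0, None)
            total = probs.sum()
            if not np.isclose(total, 1.0, atol=1e-9):
                raise InvalidParameterError(f"probabilities sum to {total}, not 1")
            probs = probs / total
        self.support = support
        self.probs = probs
        self._flat_cdf = None

    @property
    def marginal_x(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    @property
    def marginal_y(self) -> np.ndarray:
        return self.probs.sum(axis=0)

    def moments(self) -> dict:
        i = self.support.counts_x
        j = self.support.counts_y
        px = self.marginal_x
        py = self.marginal_y
        mean_x = float(i @ px)
        mean_y = float(j @ py)
        var_x = float((i - mean_x) ** 2 @ px)
        var_y = float((j - mean_y) ** 2 @ py)
        exy = float(i @ self.probs @ j)
        return {"mean_x": mean_x, "mean_y": mean_y,
                "var_x": var_x, "var_y": var_y, "exy": exy}

    def expand(self, support: TruncatedSupport) -> "TruncatedBivariatePMF":
        """Zero-pad the table onto a (weakly) larger grid."""
        if support.shape == self.support.shape:
            return self
        if (support.max_count_x < self.support.max_count_x
                or support.max_count_y < self.support.max_count_y):
            raise InvalidParameterError("expand target must contain current support")
        out = np.zeros(support.shape)
        out[: self.support.max_count_x + 1, : self.support.max_count_y + 1] = self.probs
        return TruncatedBivariatePMF(support, out, _validate=False)


@dataclass(frozen=True)
class FeasibleCorrelationRange:
    """Attainable Pearson correlations for fixed discrete marginals."""

    rho_min: float
    rho_max: float

    def contains(self, rho: float) -> bool:
        return self.rho_min <= rho <= self.rho_max

    def clip(self, rho: float, margin: float = 1e-6) -> float:
        """Pull rho inside the range, keeping a safety margin off the ends."""
        width = self.rho_max - self.rho_min
        m = min(margin, 0.49 * width)
        return float(np.clip(rho, self.rho_min + m, self.rho_max - m))


@dataclass(frozen=True)
class MaxEntModel:
    """Solved maximum entropy model: nuisance parameters plus multipliers."""

    marginal_x: MarginalSpec
    marginal_y: MarginalSpec
    correlation: float
    log_row: np.ndarray      # log a_i
    log_col: np.ndarray      # log b_j
    theta: float             # interaction exponent on i*j
    pmf: TruncatedBivariatePMF
    constraint_tol: float = DEFAULT_CONSTRAINT_TOL

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "marginal_x": {"family": self.marginal_x.family, "rate": self.marginal_x.rate},
            "marginal_y": {"family": self.marginal_y.family, "rate": self.marginal_y.rate},
            "correlation": self.correlation,
            "log_row": self.log_row.tolist(),
            "log_col": self.log_col.tolist(),
            "theta": self.theta,
            "support": [self.pmf.support.max_count_x, self.pmf.support.max_count_y],
            "constraint_tol": self.constraint_tol,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "MaxEntModel":
        text = str(text_or_path)
        if "{" not in text:  # a path, not a JSON document
            text = Path(text).read_text()
        doc = json.loads(text)
        support = TruncatedSupport(*doc["support"])
        log_row = np.asarray(doc["log_row"])
        log_col = np.asarray(doc["log_col"])
        i = support.counts_x[:, None]
        j = support.counts_y[None, :]
        logp = log_row[:, None] + log_col[None, :] + doc["theta"] * i * j
        probs = np.exp(logp - logsumexp(logp))
        return cls(
            MarginalSpec(**doc["marginal_x"]), MarginalSpec(**doc["marginal_y"]),
            doc["correlation"], log_row, log_col, doc["theta"],
            TruncatedBivariatePMF(support, probs), doc["constraint_tol"])


# ---------------------------------------------------------------------------
# operations


def truncate_support(mx: MarginalSpec, my: MarginalSpec,
                     truncation_epsilon: float = DEFAULT_TRUNCATION_EPSILON
                     ) -> TruncatedSupport:
    """Smallest grid retaining marginal mass >= 1 - epsilon per margin."""
    if not (0 < truncation_epsilon <= 1e-4):
        raise InvalidParameterError("truncation_epsilon must be in (0, 1e-4]")

    def bound(m: MarginalSpec) -> int:
        if not np.isfinite(m.rate):
            raise InvalidParameterError("non-finite rate")
        k = int(stats.poisson.ppf(1.0 - truncation_epsilon, m.rate))
        # ppf can undershoot at extreme tails; verify and walk up if needed
        while stats.poisson.cdf(k, m.rate) < 1.0 - truncation_epsilon:
            k += 1
        return max(k, 1)

    return TruncatedSupport(bound(mx), bound(my))


def _marginal_moments(p: np.ndarray) -> tuple[float, float]:
    k = np.arange(p.size)
    mean = float(k @ p)
    var = float((k - mean) ** 2 @ p)
    return mean, var


def _extreme_exy(px: np.ndarray, py: np.ndarray, *, comonotone: bool) -> float:
    """E[XY] of the comonotone (or countermonotone) coupling of px, py."""
    x_vals = np.arange(px.size)
    y_vals = np.arange(py.size)
    if not comonotone:
        y_vals = y_vals[::-1]
        py = py[::-1]
    cx = np.cumsum(px)
    cy = np.cumsum(py)
    # merge the two quantile staircases
    cuts = np.union1d(cx, cy)
    cuts = cuts[(cuts > 0) & (cuts <= 1.0 + 1e-15)]
    prev = 0.0
    exy = 0.0
    for c in cuts:
        mass = c - prev
        if mass <= 0:
            continue
        xi = x_vals[min(np.searchsorted(cx, prev + mass / 2.0), cx.size - 1)]
        yj = y_vals[min(np.searchsorted(cy, prev + mass / 2.0), cy.size - 1)]
        exy += mass * xi * yj
        prev = c
    return exy


def feasible_correlation_range(mx: MarginalSpec, my: MarginalSpec,
                               support: TruncatedSupport
                               ) -> FeasibleCorrelationRange:
    """Correlation bounds attained by quantile (counter)monotone couplings."""
    px = mx.pmf(support.max_count_x)
    py = my.pmf(support.max_count_y)
    mean_x, var_x = _marginal_moments(px)
    mean_y, var_y = _marginal_moments(py)
    if var_x <= 0 or var_y <= 0:
        raise DegenerateMarginalError("marginal has zero variance on this support")
    denom = np.sqrt(var_x * var_y)
    hi = (_extreme_exy(px, py, comonotone=True) - mean_x * mean_y) / denom
    lo = (_extreme_exy(px, py, comonotone=False) - mean_x * mean_y) / denom
    return FeasibleCorrelationRange(float(max(lo, -1.0)), float(min(hi, 1.0)))


def entropy(p: TruncatedBivariatePMF | np.ndarray) -> float:
    """Shannon entropy in bits: -sum p log2 p over nonzero entries."""
    probs = p.probs if isinstance(p, TruncatedBivariatePMF) else np.asarray(p)
    return float(-xlogy(probs, probs).sum() / np.log(2.0))


def pearson_correlation(p: TruncatedBivariatePMF) -> float:
    """Exact Pearson correlation of the table."""
    m = p.moments()
    if m["var_x"] <= 0 or m["var_y"] <= 0:
        raise DegenerateMarginalError("zero marginal variance")
    r = (m["exy"] - m["mean_x"] * m["mean_y"]) / np.sqrt(m["var_x"] * m["var_y"])
    return float(np.clip(r, -1.0, 1.0))


def sample(p: TruncatedBivariatePMF, n: int,
           seed: int | np.random.Generator | None = None) -> CountPairSample:
    """n i.i.d. draws by inverse CDF on the flattened table."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if p._flat_cdf is None:
        p._flat_cdf = np.cumsum(p.probs.ravel())
    idx = np.searchsorted(p._flat_cdf, rng.random(n) * p._flat_cdf[-1],
                          side="right")
    idx = np.minimum(idx, p.probs.size - 1)
    xs, ys = np.unravel_index(idx, p.probs.shape)
    return CountPairSample(xs, ys)


# ---------------------------------------------------------------------------
# solver


def _sinkhorn(log_px, log_py, kernel_log, a, b, tol, max_iter):
    """IPF in log domain: alternate row/column matching until stationary."""
    for _ in range(max_iter):
        a_new = log_px - logsumexp(b[None, :] + kernel_log, axis=1)
        b_new = log_py - logsumexp(a_new[:, None] + kernel_log, axis=0)
        delta = max(np.abs(a_new - a).max(), np.abs(b_new - b).max())
        a, b = a_new, b_new
        if delta < tol:
            break
    return a, b


def _sinkhorn_linear(px, py, kernel, u, v, tol, max_iter):
    """IPF by row/column scaling; returns None on overflow (caller falls back)."""
    for _ in range(max_iter):
        u_new = px / (kernel @ v)
        v_new = py / (kernel.T @ u_new)
        if not (np.all(np.isfinite(u_new)) and np.all(np.isfinite(v_new))):
            return None
        delta = max(np.abs(np.log(u_new / u)).max(), np.abs(np.log(v_new / v)).max())
        u, v = u_new, v_new
        if delta < tol:
            break
    return u, v


def fit_maxent(mx: MarginalSpec, my: MarginalSpec, rho: float,
               support: TruncatedSupport | None = None,
               constraint_tol: float = DEFAULT_CONSTRAINT_TOL) -> MaxEntModel:
    """Solve the maximum entropy program for fixed marginals and correlation.

    Raises
    ------
    FeasibilityError
        If ``rho`` lies outside the attainable range for these marginals.
    ConvergenceError
        If the scaling/root-solve loop cannot meet ``constraint_tol``.
    """
    if support is None:
        support = truncate_support(mx, my)
    px = mx.pmf(support.max_count_x)
    py = my.pmf(support.max_count_y)
    mean_x, var_x = _marginal_moments(px)
    mean_y, var_y = _marginal_moments(py)
    if var_x <= 0 or var_y <= 0:
        raise DegenerateMarginalError("marginal has zero variance on this support")

    i = support.counts_x.astype(float)
    j = support.counts_y.astype(float)
    ij = np.outer(i, j)
    log_px = np.log(px)
    log_py = np.log(py)

    if abs(rho) < 1e-9:  # numerically indistinguishable from independence
        probs = np.outer(px, py)
        return MaxEntModel(mx, my, 0.0, log_px, log_py, 0.0,
                           TruncatedBivariatePMF(support, probs, _validate=False),
                           constraint_tol)

    rng_feas = feasible_correlation_range(mx, my, support)
    if not (rng_feas.rho_min < rho < rng_feas.rho_max):
        raise FeasibilityError(
            f"rho={rho} outside attainable range "
            f"({rng_feas.rho_min:.6f}, {rng_feas.rho_max:.6f})",
            rng_feas.rho_min, rng_feas.rho_max)

    target_exy = rho * np.sqrt(var_x * var_y) + mean_x * mean_y
    ipf_tol = min(1e-13, constraint_tol * 1e-3)

    # warm-started scaling factors reused across theta evaluations
    state = {"a": log_px.copy(), "b": log_py.copy()}

    def solve_probs(theta: float) -> np.ndarray:
        klog = theta * ij
        # fast path: plain scaling when the kernel cannot overflow badly
        if abs(theta) * ij.max() < 500.0:
            res = _sinkhorn_linear(px, py, np.exp(klog),
                                   np.exp(state["a"]), np.exp(state["b"]),
                                   ipf_tol, _MAX_ITER)
        else:
            res = None
        if res is not None:
            u, v = res
            with np.errstate(divide="ignore"):
                state["a"], state["b"] = np.log(u), np.log(v)
            probs = (u[:, None] * v[None, :]) * np.exp(klog)
        else:
            state["a"], state["b"] = _sinkhorn(log_px, log_py, klog,
                                               state["a"], state["b"],
                                               ipf_tol, _MAX_ITER)
            probs = np.exp(state["a"][:, None] + state["b"][None, :] + klog)
        return probs / probs.sum()

    def exy_gap(theta: float) -> float:
        return float((solve_probs(theta) * ij).sum() - target_exy)

    # E[XY] is strictly increasing in theta; bracket by doubling
    lo, hi = (0.0, 0.25) if rho > 0 else (-0.25, 0.0)
    for _ in range(80):
        if rho > 0:
            if exy_gap(hi) > 0:
                break
            lo, hi = hi, hi * 2.0
        else:
            if exy_gap(lo) < 0:
                break
            lo, hi = lo * 2.0, lo
    else:
        raise ConvergenceError("could not bracket the interaction exponent",
                               {"target_exy": target_exy})

    theta = optimize.brentq(exy_gap, lo, hi, xtol=1e-13, rtol=8.9e-16,
                            maxiter=200)
    probs = solve_probs(theta)

    resid_marg = max(np.abs(probs.sum(axis=1) - px).max(),
                     np.abs(probs.sum(axis=0) - py).max())
    fitted_rho = ((probs * ij).sum() - mean_x * mean_y) / np.sqrt(var_x * var_y)
    resid_rho = abs(fitted_rho - rho)
    if resid_marg > constraint_tol or resid_rho > max(constraint_tol, 1e-9):
        raise ConvergenceError(
            "maximum entropy solver did not reach tolerance",
            {"marginal_residual": resid_marg, "rho_residual": resid_rho})

    return MaxEntModel(mx, my, float(rho), state["a"].copy(), state["b"].copy(),
                       float(theta),
                       TruncatedBivariatePMF(support, probs, _validate=False),
                       constraint_tol)
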