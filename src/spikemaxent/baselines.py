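"""Comparison and auxiliary tests around the Monte Carlo maximum entropy test.

* Likelihood ratio test of the maximum entropy model (reduced, 3 parameters)
  against the saturated multinomial model on the count grid, with the
  asymptotic chi-square reference distribution.  For small samples the
  chi-square approximation is poor, which is exactly why the Monte Carlo
  test exists; this baseline quantifies that gap.
* Benjamini–Hochberg step-up FDR control for multi-pair / multi-bin scans.
* Poisson goodness-of-fit checks for single neurons: a Monte Carlo GOF test
  on the count histogram (entropy-difference statistic, rate as nuisance) and
  a Kolmogorov–Smirnov test of time-rescaled interspike intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .data import CountPairSample
from .errors import InsufficientDataError, InvalidParameterError
from .maxent import (
    MarginalSpec,
    TruncatedSupport,
    fit_maxent,
    feasible_correlation_range,
    truncate_support,
)
from .mctest import NuisanceParams, mc_p_value

__all__ = [
    "LRTestResult",
    "FDRResult",
    "lr_test",
    "bh_procedure",
    "poisson_gof_mc",
    "time_rescaling_ks",
]

_LOG2 = np.log(2.0)
_RATE_FLOOR = 1e-2


@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    df: int
    p_value: float
    ml_me_params: NuisanceParams
    loglik_full: float
    loglik_me: float


@dataclass(frozen=True)
class FDRResult:
    raw_p: np.ndarray
    rejected: np.ndarray
    threshold_index: int
    alpha: float

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def _me_table(rate_x: float, rate_y: float, rho: float,
              min_x: int, min_y: int):
    mx = MarginalSpec(max(rate_x, _RATE_FLOOR))
    my = MarginalSpec(max(rate_y, _RATE_FLOOR))
    base = truncate_support(mx, my)
    support = TruncatedSupport(max(base.max_count_x, min_x),
                               max(base.max_count_y, min_y))
    if rho != 0.0:
        feas = feasible_correlation_range(mx, my, support)
        rho = feas.clip(rho)
    return fit_maxent(mx, my, rho, support)


def lr_test(data: CountPairSample,
            support: TruncatedSupport | None = None) -> LRTestResult:
    """Likelihood ratio test: saturated multinomial vs maximum entropy model.

    The full-model MLE is the empirical frequency table; the reduced-model
    MLE maximizes the ME likelihood over (rate_x, rate_y, rho) numerically
    from the sample estimates.  Degrees of freedom: (#grid cells - 1) - 3.
    """
    if data.n < 2:
        raise InvalidParameterError("likelihood ratio test needs n >= 2")
    xs, ys = data.xs, data.ys
    n = data.n
    # saturated log-likelihood from the observed cell counts
    _, cell_counts = np.unique(np.column_stack([xs, ys]), axis=0,
                               return_counts=True)
    loglik_full = float(xlogy(cell_counts, cell_counts / n).sum())

    mx0, my0, r0 = data.sample_statistics()
    min_x, min_y = int(xs.max()), int(ys.max())

    def neg_loglik(theta: np.ndarray) -> float:
        rx, ry = np.exp(theta[0]), np.exp(theta[1])
        rho = float(np.tanh(theta[2]))
        if rx > 1e3 or ry > 1e3:
            return 1e12
        try:
            model = _me_table(rx, ry, rho, min_x, min_y)
        except Exception:
            return 1e12
        logp = np.log(np.clip(model.pmf.probs[xs, ys], 1e-300, None))
        return -float(logp.sum())

    x0 = np.array([np.log(max(mx0, _RATE_FLOOR)), np.log(max(my0, _RATE_FLOOR)),
                   np.arctanh(np.clip(r0, -0.95, 0.95))])
    res = optimize.minimize(neg_loglik, x0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-6,
                                     "maxiter": 400})
    loglik_me = -float(res.fun)
    best = NuisanceParams(max(float(np.exp(res.x[0])), _RATE_FLOOR),
                          max(float(np.exp(res.x[1])), _RATE_FLOOR),
                          float(np.tanh(res.x[2])))
    model = _me_table(best.rate_x, best.rate_y, best.rho, min_x, min_y)
    statistic = max(2.0 * (loglik_full - loglik_me), 0.0)
    df = model.pmf.support.size - 1 - 3
    p = float(stats.chi2.sf(statistic, df))
    return LRTestResult(statistic, df, p, best, loglik_full, loglik_me)


def bh_procedure(p_values, alpha: float = 0.05) -> FDRResult:
    """Benjamini–Hochberg step-up rule at FDR level alpha."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FDRResult(p, np.zeros(0, dtype=bool), 0, alpha)
    if (p < 0).any() or (p > 1).any():
        raise InvalidParameterError("p-values must lie in [0, 1]")
    rejected = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    order = np.sort(p)
    m = p.size
    ks = np.nonzero(order <= (np.arange(1, m + 1) * alpha / m))[0]
    threshold_index = int(ks[-1] + 1) if ks.size else 0
    return FDRResult(p, rejected, threshold_index, alpha)


def _poisson_hist_entropy_gap(freqs: np.ndarray, rate: float) -> float:
    """|H(empirical histogram) - H(truncated Poisson(rate))| in bits."""
    k = freqs.size - 1
    pmf = stats.poisson.pmf(np.arange(k + 1), rate)
    pmf = pmf / pmf.sum()
    h_emp = -xlogy(freqs, freqs).sum() / _LOG2
    h_ref = -xlogy(pmf, pmf).sum() / _LOG2
    return abs(h_emp - h_ref)


def poisson_gof_mc(counts, n_mc: int = 199,
                   seed: int | np.random.Generator | None = None,
                   anneal_steps: int = 30) -> float:
    """Monte Carlo GOF test of the Poisson hypothesis for one neuron.

    Statistic: entropy difference between the empirical count histogram and
    the (truncated) Poisson pmf at the candidate rate.  The p-value is
    maximized over the rate by a short 1-D anneal confined to a confidence
    interval around the sample mean, mirroring the bivariate test's
    nuisance treatment.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size == 0:
        raise InvalidParameterError("counts must be nonempty")
    n = counts.size
    mean = counts.mean()
    if mean <= 0:
        return 1.0  # degenerate all-zero sample: Poisson(0+) fits exactly
    rng_master = np.random.default_rng(seed)
    se = np.sqrt(mean / n)
    box = (max(mean - 2.0 * se, _RATE_FLOOR), mean + 2.0 * se)

    def eval_p(rate: float, rng) -> float:
        bound = max(int(stats.poisson.ppf(1.0 - 1e-10, rate)), int(counts.max()), 1)
        pmf = stats.poisson.pmf(np.arange(bound + 1), rate)
        pmf = pmf / pmf.sum()
        emp = np.bincount(counts, minlength=bound + 1) / n
        d0 = _poisson_hist_entropy_gap(emp, rate)
        cdf = np.cumsum(pmf)
        idx = np.searchsorted(cdf, rng.random((n_mc, n)) * cdf[-1], "right")
        np.minimum(idx, bound, out=idx)
        idx += (np.arange(n_mc) * (bound + 1))[:, None]
        f = np.bincount(idx.ravel(), minlength=n_mc * (bound + 1))
        f = f.reshape(n_mc, bound + 1) / n
        h_ref = -xlogy(pmf, pmf).sum() / _LOG2
        divs = np.abs(-xlogy(f, f).sum(axis=1) / _LOG2 - h_ref)
        return mc_p_value(d0, divs, rng)

    rate = float(mean)
    p_best = p_cur = eval_p(rate, rng_master)
    temp = 0.1
    for _ in range(anneal_steps):
        prop = float(np.clip(rate + rng_master.normal(0.0, 0.5 * se), *box))
        p_new = eval_p(prop, rng_master)
        p_best = max(p_best, p_new)
        if p_new >= p_cur or rng_master.random() < np.exp((p_new - p_cur) / temp):
            rate, p_cur = prop, p_new
        temp *= 0.9
    return float(p_best)


def time_rescaling_ks(train, rate_per_bin, bin_s: float) -> float:
    """KS test of time-rescaled interspike intervals against Exp(1).

    Under a (possibly inhomogeneous, piecewise-constant rate) Poisson
    process, intervals rescaled by the integrated rate are unit exponential;
    mapping 1 - exp(-tau) sends them to Uniform(0, 1), against which the
    Kolmogorov–Smirnov statistic is computed.
    """
    if bin_s <= 0:
        raise InvalidParameterError("bin width must be positive")
    times = np.asarray(train.times, dtype=float)
    if times.size < 2:
        raise InsufficientDataError("time rescaling needs at least 2 spikes")
    rate = np.asarray(rate_per_bin, dtype=float)
    if (rate < 0).any():
        raise InvalidParameterError("rates must be nonnegative")
    n_bins_needed = int(np.ceil(times[-1] / bin_s)) + 1
    if rate.size < n_bins_needed:   # extend with the last rate
        rate = np.concatenate([rate,
                               np.full(n_bins_needed - rate.size, rate[-1])])
    edges = np.arange(rate.size + 1) * bin_s
    cum = np.concatenate([[0.0], np.cumsum(rate * bin_s)])
    big_lambda = np.interp(times, edges, cum)
    taus = np.diff(big_lambda)
    u = 1.0 - np.exp(-taus)
    return float(stats.kstest(u, "uniform").pvalue)
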