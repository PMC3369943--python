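"""Monte Carlo goodness-of-fit test with nuisance-parameter maximization.

The null hypothesis is that the observed count pairs were drawn from *some*
maximum entropy distribution with Poisson marginals and a linear correlation
coefficient.  For a fixed candidate parameter triple (rate_x, rate_y, rho) the
test draws Monte Carlo datasets of the same size as the data from the fitted
reference, ranks the observed divergence within the Monte Carlo divergences
(randomized tie breaking keeps the discrete statistic exact), and converts the
rank into a p-value with the finite-sample correction

    p = (#{k : (d_k, u_k) >= (d_0, u_0)} + 1) / (N + 1).

Because the parameters are unknown nuisance quantities, the p-value is then
*maximized* over them by simulated annealing, and the worst-case (largest)
p-value is reported.  This construction guarantees the false rejection rate
stays below the significance level regardless of the true parameter values.

For the mutual-information variant the nuisance space holds one parameter
triple per stimulus and Monte Carlo draws copy the data's per-stimulus trial
allocation exactly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import xlogy

from .data import CountPairSample
from .divergences import DivergenceMeasure, StimulusEnsemble, empirical_pmf
from .errors import InvalidParameterError, LabelingError
from .maxent import (
    MarginalSpec,
    MaxEntModel,
    TruncatedBivariatePMF,
    entropy,
    feasible_correlation_range,
    fit_maxent,
    truncate_support,
)

__all__ = [
    "NuisanceParams",
    "AnnealConfig",
    "MCTestResult",
    "mc_p_value",
    "evaluate_p",
    "optimize_nuisance",
    "run_test",
]

logger = logging.getLogger(__name__)

_LOG2 = np.log(2.0)
_RATE_FLOOR = 1e-2
_RHO_CLIP_MARGIN = 1e-6


@dataclass(frozen=True)
class NuisanceParams:
    """One candidate null: two Poisson rates and a correlation coefficient."""

    rate_x: float
    rate_y: float
    rho: float

    def __post_init__(self):
        if self.rate_x <= 0 or self.rate_y <= 0:
            raise InvalidParameterError("rates must be positive")
        if not -1.0 < self.rho < 1.0:
            raise InvalidParameterError("rho must lie in (-1, 1)")

    def as_dict(self) -> dict:
        return {"rate_x": self.rate_x, "rate_y": self.rate_y, "rho": self.rho}


@dataclass(frozen=True)
class AnnealConfig:
    """Simulated-annealing budget for the p-value maximization.

    The p-value lives on a lattice of pitch 1/(N+1), so temperatures are in
    p-value units.  Proposals are Gaussian per parameter with standard
    deviations expressed in units of the parameter's estimated standard
    error, and the search is confined to a per-parameter confidence box
    around the sample estimates.  The maximization exists to protect the
    level against estimation error in the nuisance parameters, so the search
    is scoped to that estimation uncertainty: over an unbounded space a
    scalar divergence can always be absorbed (a rate exists whose reference
    entropy matches the plug-in entropy exactly), which annihilates power
    while adding nothing to validity.
    """

    initial_temperature: float = 0.1
    cooling_factor: float = 0.95
    steps: int = 15
    #: proposal sd for each rate, in units of its standard error sqrt(rate/n)
    rate_proposal_scale: float = 0.5
    #: proposal sd for rho, in units of the Fisher-z standard error
    rho_proposal_scale: float = 0.5
    seed: int | np.random.SeedSequence | None = None
    common_random_numbers: bool = False
    #: confidence level of the per-parameter search box (Wald interval for
    #: rates, Fisher-z interval for rho) around the sample estimates
    confidence_level: float = 0.95

    def __post_init__(self):
        if self.steps < 1:
            raise InvalidParameterError("steps must be >= 1")
        if not 0.0 < self.cooling_factor < 1.0:
            raise InvalidParameterError("cooling_factor must be in (0, 1)")


@dataclass
class MCTestResult:
    """Outcome of the full test: worst-case p-value and audit trail."""

    p_value: float
    d0: float
    mc_divergences: np.ndarray
    tie_breakers: np.ndarray
    best_params: NuisanceParams | dict
    trace: list
    rejected: bool
    n_mc: int
    alpha: float
    divergence: str

    def to_json(self, path: str | Path | None = None) -> str:
        def params_doc(p):
            if isinstance(p, NuisanceParams):
                return p.as_dict()
            return {str(k): v.as_dict() for k, v in p.items()}

        doc = {
            "p_value": self.p_value,
            "d0": self.d0,
            "mc_divergences": np.asarray(self.mc_divergences).tolist(),
            "tie_breakers": np.asarray(self.tie_breakers).tolist(),
            "best_params": params_doc(self.best_params),
            "trace": [{"params": params_doc(p), "p": pv} for p, pv in self.trace],
            "rejected": bool(self.rejected),
            "n_mc": self.n_mc,
            "alpha": self.alpha,
            "divergence": self.divergence,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# p-value from divergence ranks


def mc_p_value(d0: float, mc_divs: Sequence[float],
               seed: int | np.random.Generator | None = None,
               return_marks: bool = False):
    """Randomized rank p-value of d0 among the Monte Carlo divergences.

    Uniform marks attached to every statistic order exact ties randomly
    (a tied pair is decided by a coin toss), which keeps the test exact for
    discrete statistics.
    """
    mc_divs = np.asarray(mc_divs, dtype=float)
    if mc_divs.size < 1:
        raise InvalidParameterError("need at least one Monte Carlo divergence")
    if not (np.isfinite(d0) and np.all(np.isfinite(mc_divs))):
        raise InvalidParameterError("divergences must be finite")
    rng = np.random.default_rng(seed)
    u = rng.random(mc_divs.size + 1)
    u0, u_mc = u[0], u[1:]
    exceed = np.count_nonzero((mc_divs > d0) | ((mc_divs == d0) & (u_mc >= u0)))
    p = (exceed + 1) / (mc_divs.size + 1)
    if return_marks:
        return float(p), u
    return float(p)


# ---------------------------------------------------------------------------
# single p evaluation at fixed nuisance parameters


def _fit_clipped(params: NuisanceParams, constraint_tol: float = 1e-9
                 ) -> MaxEntModel:
    """Fit the ME reference, clipping an infeasible rho into range."""
    mx = MarginalSpec(max(params.rate_x, _RATE_FLOOR))
    my = MarginalSpec(max(params.rate_y, _RATE_FLOOR))
    support = truncate_support(mx, my)
    rho = params.rho
    if rho != 0.0:
        feas = feasible_correlation_range(mx, my, support)
        clipped = feas.clip(rho, _RHO_CLIP_MARGIN)
        if clipped != rho:
            logger.debug("clipped rho %.4f -> %.4f into feasible range",
                         rho, clipped)
            rho = clipped
    return fit_maxent(mx, my, rho, support, constraint_tol)


def _mc_count_tables(ref: TruncatedBivariatePMF, n: int, n_mc: int,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_mc, cells) empirical frequency tables of n draws each from ref."""
    flat = ref.probs.ravel()
    cdf = np.cumsum(flat)
    k = flat.size
    idx = np.searchsorted(cdf, rng.random((n_mc, n)) * cdf[-1], side="right")
    np.minimum(idx, k - 1, out=idx)
    idx += (np.arange(n_mc) * k)[:, None]
    counts = np.bincount(idx.ravel(), minlength=n_mc * k).reshape(n_mc, k)
    return counts / n


def _entropies_bits(freqs: np.ndarray) -> np.ndarray:
    return -xlogy(freqs, freqs).sum(axis=-1) / _LOG2


def _evaluate_pair(data: CountPairSample, params: NuisanceParams,
                   divergence: DivergenceMeasure, n_mc: int,
                   rng: np.random.Generator):
    model = _fit_clipped(params)
    ref = model.pmf
    emp = empirical_pmf(data, ref.support)
    d0 = divergence(emp, ref.expand(emp.support))
    if divergence.name == "entropy_diff":
        freqs = _mc_count_tables(ref, data.n, n_mc, rng)
        divs = np.abs(_entropies_bits(freqs) - entropy(ref))
    else:
        from .maxent import sample as draw
        divs = np.empty(n_mc)
        for m in range(n_mc):
            s = draw(ref, data.n, rng)
            e = empirical_pmf(s, ref.support)
            divs[m] = divergence(e, ref.expand(e.support))
    p, u = mc_p_value(d0, divs, rng, return_marks=True)
    return p, float(d0), divs, u


def _build_ensemble(params: Mapping, labels: Sequence) -> StimulusEnsemble:
    conds = []
    for lab in labels:
        conds.append(_fit_clipped(params[lab]).pmf)
    return StimulusEnsemble(tuple(labels), tuple(conds))


def _mi_bits(conds: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """MI for a batch of conditional tables: conds is (..., S, cells)."""
    pr = prior.reshape((1,) * (conds.ndim - 2) + (-1, 1))
    mix = (pr * conds).sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(conds > 0, conds / np.where(mix > 0, mix, 1.0), 1.0)
        terms = pr * conds * np.log(ratio)
    return terms.sum(axis=(-2, -1)) / _LOG2


def _evaluate_mi(data: CountPairSample, params: Mapping,
                 divergence: DivergenceMeasure, n_mc: int,
                 rng: np.random.Generator):
    labels = sorted(params.keys(), key=str)
    ens = _build_ensemble(params, labels)
    d0 = divergence(data, ens)
    per_stim = data.by_stimulus()
    alloc = {lab: per_stim[lab].n for lab in labels}
    cells = ens.support.size
    S = len(labels)
    mc_conds = np.empty((n_mc, S, cells))
    for s_idx, lab in enumerate(labels):
        ref = ens.conditional_refs[s_idx]
        mc_conds[:, s_idx, :] = _mc_count_tables(ref, alloc[lab], n_mc, rng)
    ref_conds = np.stack([c.probs.ravel() for c in ens.conditional_refs])
    i_ref = float(_mi_bits(ref_conds[None], ens.prior)[0])
    divs = np.abs(_mi_bits(mc_conds, ens.prior) - i_ref)
    p, u = mc_p_value(d0, divs, rng, return_marks=True)
    return p, float(d0), divs, u


def _evaluate(data, params, divergence, n_mc, rng):
    if isinstance(params, NuisanceParams):
        return _evaluate_pair(data, params, divergence, n_mc, rng)
    return _evaluate_mi(data, params, divergence, n_mc, rng)


def evaluate_p(data: CountPairSample, params: NuisanceParams | Mapping,
               divergence: DivergenceMeasure, n_mc: int,
               seed: int | np.random.Generator | None = None) -> float:
    """p-value at fixed nuisance parameters (no maximization)."""
    if n_mc < 19:
        raise InvalidParameterError("n_mc must be >= 19 for a usable p lattice")
    rng = np.random.default_rng(seed)
    return _evaluate(data, params, divergence, n_mc, rng)[0]


# ---------------------------------------------------------------------------
# nuisance maximization


def _initial_params(data: CountPairSample, labelled: bool):
    if not labelled:
        mx, my, r = data.sample_statistics()
        return NuisanceParams(max(mx, _RATE_FLOOR), max(my, _RATE_FLOOR),
                              float(np.clip(r, -0.99, 0.99)))
    out = {}
    for lab, sub in data.by_stimulus().items():
        mx, my, r = sub.sample_statistics()
        out[lab] = NuisanceParams(max(mx, _RATE_FLOOR), max(my, _RATE_FLOOR),
                                  float(np.clip(r, -0.99, 0.99)))
    return out


def _param_box(sub: CountPairSample, level: float) -> dict:
    """Per-parameter confidence box around the sample estimates.

    Rates get a Wald interval for a Poisson mean; rho gets a Fisher-z
    interval.  The box is the search domain of the anneal.
    """
    from scipy import stats as _st

    z = float(_st.norm.ppf(0.5 * (1.0 + level)))
    n = sub.n
    mx, my, r = sub.sample_statistics()

    def rate_box(mean: float) -> tuple[float, float]:
        mean = max(mean, _RATE_FLOOR)
        half = z * np.sqrt(mean / n)
        return (max(mean - half, _RATE_FLOOR), mean + half + _RATE_FLOOR)

    if n > 3 and abs(r) < 1.0:
        zr = np.arctanh(np.clip(r, -0.999, 0.999))
        half = z / np.sqrt(n - 3)
        rho_box = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    else:
        rho_box = (-0.999, 0.999)
    return {"rate_x": rate_box(mx), "rate_y": rate_box(my), "rho": rho_box,
            "n": n}


def _boxes_for(data: CountPairSample, labelled: bool, level: float):
    if not labelled:
        return _param_box(data, level)
    return {lab: _param_box(sub, level)
            for lab, sub in data.by_stimulus().items()}


def _perturb_one(p: NuisanceParams, box: dict, cfg: AnnealConfig,
                 rng: np.random.Generator) -> NuisanceParams:
    n = box["n"]
    se_x = np.sqrt(p.rate_x / n)
    se_y = np.sqrt(p.rate_y / n)
    se_rho = 1.0 / np.sqrt(max(n - 3, 4))
    rx = p.rate_x + rng.normal(0.0, cfg.rate_proposal_scale * se_x)
    ry = p.rate_y + rng.normal(0.0, cfg.rate_proposal_scale * se_y)
    rho = p.rho + rng.normal(0.0, cfg.rho_proposal_scale * se_rho)
    return NuisanceParams(
        float(np.clip(rx, *box["rate_x"])),
        float(np.clip(ry, *box["rate_y"])),
        float(np.clip(rho, max(box["rho"][0], -0.999),
                      min(box["rho"][1], 0.999))))


def _perturb(params, boxes, cfg, rng):
    if isinstance(params, NuisanceParams):
        return _perturb_one(params, boxes, cfg, rng)
    return {lab: _perturb_one(p, boxes[lab], cfg, rng)
            for lab, p in params.items()}


def optimize_nuisance(data: CountPairSample, divergence: DivergenceMeasure,
                      cfg: AnnealConfig | None = None, n_mc: int = 999,
                      alpha: float = 0.05) -> MCTestResult:
    """Maximize the Monte Carlo p-value over the nuisance parameters.

    Starts from the sample means and sample correlation, proposes Gaussian
    moves inside a per-parameter confidence box around those estimates
    (see :class:`AnnealConfig`), always accepts p increases, accepts
    decreases with Metropolis probability exp((p_new - p_cur)/T) under
    geometric cooling, and reports the maximum p encountered together with
    its parameters.
    """
    cfg = cfg or AnnealConfig()
    ss = (cfg.seed if isinstance(cfg.seed, np.random.SeedSequence)
          else np.random.SeedSequence(cfg.seed))
    prop_rng = np.random.default_rng(ss.spawn(1)[0])
    eval_seeds = ss.spawn(cfg.steps + 1)

    def eval_rng(i):
        return np.random.default_rng(eval_seeds[0] if cfg.common_random_numbers
                                     else eval_seeds[i])

    params = _initial_params(data, divergence.needs_labels)
    boxes = _boxes_for(data, divergence.needs_labels, cfg.confidence_level)
    p_cur, d0, divs, u = _evaluate(data, params, divergence, n_mc, eval_rng(0))
    best = {"p": p_cur, "params": params, "d0": d0, "divs": divs, "u": u}
    trace = [(params, p_cur)]
    temp = cfg.initial_temperature
    for step in range(1, cfg.steps + 1):
        proposal = _perturb(params, boxes, cfg, prop_rng)
        p_new, d0n, divsn, un = _evaluate(data, proposal, divergence, n_mc,
                                          eval_rng(step))
        trace.append((proposal, p_new))
        if p_new > best["p"]:
            best = {"p": p_new, "params": proposal, "d0": d0n,
                    "divs": divsn, "u": un}
        if p_new >= p_cur or prop_rng.random() < math.exp((p_new - p_cur) / temp):
            params, p_cur = proposal, p_new
        temp *= cfg.cooling_factor
    return MCTestResult(
        p_value=best["p"], d0=best["d0"], mc_divergences=best["divs"],
        tie_breakers=best["u"], best_params=best["params"], trace=trace,
        rejected=best["p"] < alpha, n_mc=n_mc, alpha=alpha,
        divergence=divergence.name)


def run_test(data: CountPairSample, divergence: DivergenceMeasure,
             alpha: float = 0.05, n_mc: int = 999,
             cfg: AnnealConfig | None = None) -> MCTestResult:
    """Full test: initialize, anneal the p-value, decide at level alpha.

    Rejection is strict: the null is rejected when the worst-case p-value
    falls strictly below ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError("alpha must be in (0, 1)")
    if divergence.needs_labels and not data.labelled:
        raise LabelingError(f"{divergence.name} requires stimulus labels")
    if not divergence.needs_labels and data.labelled:
        logger.info("sample carries stimulus labels; %s ignores them",
                    divergence.name)
    return optimize_nuisance(data, divergence, cfg, n_mc, alpha)
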