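"""Experiment runners: simulation studies and multi-pair dataset scans.

Each runner sweeps a factor grid, runs independent replications per cell,
and tabulates rejection fractions with binomial confidence intervals.
Per-cell random seeds derive deterministically from the base seed and the
cell's position in the enumeration order, so the whole study is reproducible
and cells are independent work units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .baselines import lr_test, time_rescaling_ks, bh_procedure
from .data import CountPairSample
from .divergences import ENTROPY_DIFF, get_divergence
from .generators import build_mixture_model
from .maxent import MarginalSpec, fit_maxent, sample, truncate_support
from .mctest import AnnealConfig, run_test
from .spikes import GammaProcessSpec, bin_counts, simulate_gamma_train

__all__ = [
    "ExperimentGrid",
    "RejectionSummary",
    "run_power_study",
    "run_lr_comparison",
    "run_autocorrelation_study",
    "run_dataset_scan",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentGrid:
    """Factor grids and budgets for a simulation study."""

    n_values: tuple[int, ...] = (10, 50, 100, 200)
    rho_values: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    m_values: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    gamma_values: tuple[float, ...] = (1.0, 1.25, 1.5, 2.0)
    rate: float = 3.0
    rate_hz: float = 30.0
    bin_ms: float = 100.0
    replications: int = 100
    n_mc: int = 999
    alpha: float = 0.05
    base_seed: int = 0
    anneal_steps: int = 15
    mixture_family: str = "M1"

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("replications must be >= 1")

    def anneal_config(self, seed: int) -> AnnealConfig:
        return AnnealConfig(steps=self.anneal_steps, seed=seed)


@dataclass
class RejectionSummary:
    """Per-cell rejection fractions with binomial confidence intervals."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _cell_seed(base_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))


def _summarize(rows: list[dict], metadata: dict) -> RejectionSummary:
    df = pd.DataFrame(rows)
    lo, hi = proportion_confint(df["n_rejected"], df["replications"],
                                alpha=0.05, method="wilson")
    df["fraction"] = df["n_rejected"] / df["replications"]
    df["ci_low"] = lo
    df["ci_high"] = hi
    return RejectionSummary(df, metadata)


def run_power_study(grid: ExperimentGrid) -> RejectionSummary:
    """Rejection rates of the ME test on ME, M1 and M2 data.

    ME cells sweep the correlation coefficient (pure Type I study); M1/M2
    cells sweep the mixture parameter m (power against higher-order
    structure at fixed marginals and correlation).
    """
    rows = []
    cell = 0
    cells = ([("ME", r) for r in grid.rho_values]
             + [("M1", m) for m in grid.m_values]
             + [("M2", m) for m in grid.m_values])
    for n in grid.n_values:
        for family, value in cells:
            ss = _cell_seed(grid.base_seed, cell)
            cell += 1
            if family == "ME":
                mx = my = MarginalSpec(grid.rate)
                table = fit_maxent(mx, my, value, truncate_support(mx, my)).pmf
            else:
                table = build_mixture_model(family, value, grid.rate).pmf
            n_rej = 0
            for rep_ss in ss.spawn(grid.replications):
                data_seed, test_seed = rep_ss.spawn(2)
                data = sample(table, n, np.random.default_rng(data_seed))
                res = run_test(data, ENTROPY_DIFF, grid.alpha, grid.n_mc,
                               grid.anneal_config(test_seed))
                n_rej += res.rejected
            logger.info("power cell family=%s value=%.2f n=%d -> %d/%d",
                        family, value, n, n_rej, grid.replications)
            rows.append({"family": family, "parameter": value, "n": n,
                         "n_rejected": n_rej,
                         "replications": grid.replications})
    return _summarize(rows, {"experiment": "power", "grid": repr(grid)})


def run_lr_comparison(grid: ExperimentGrid,
                      rho_range: tuple[float, float] = (0.0, 0.5)
                      ) -> RejectionSummary:
    """Paired ME-test vs likelihood-ratio-test rejection rates.

    Panel "null": data from ME models with correlation drawn uniformly from
    ``rho_range`` (Type I error of both tests).  Panel "mixture": data from
    the copula mixture family with m ~ Uniform(0, 1) (power).  Both tests
    see identical datasets.
    """
    rows = []
    cell = 0
    for panel in ("null", "mixture"):
        for n in grid.n_values:
            ss = _cell_seed(grid.base_seed, cell)
            cell += 1
            rej_mc = rej_lr = 0
            for rep_ss in ss.spawn(grid.replications):
                par_seed, data_seed, test_seed = rep_ss.spawn(3)
                rng_par = np.random.default_rng(par_seed)
                if panel == "null":
                    rho = float(rng_par.uniform(*rho_range))
                    mx = my = MarginalSpec(grid.rate)
                    table = fit_maxent(mx, my, rho,
                                       truncate_support(mx, my)).pmf
                else:
                    m = float(rng_par.uniform(0.0, 1.0))
                    table = build_mixture_model(grid.mixture_family, m,
                                                grid.rate).pmf
                data = sample(table, n, np.random.default_rng(data_seed))
                res = run_test(data, ENTROPY_DIFF, grid.alpha, grid.n_mc,
                               grid.anneal_config(test_seed))
                rej_mc += res.rejected
                rej_lr += lr_test(data).p_value < grid.alpha
            for test_name, n_rej in (("mc_maxent", rej_mc),
                                     ("likelihood_ratio", rej_lr)):
                rows.append({"panel": panel, "test": test_name, "n": n,
                             "n_rejected": n_rej,
                             "replications": grid.replications})
    return _summarize(rows, {"experiment": "lr_comparison", "grid": repr(grid)})


def run_autocorrelation_study(grid: ExperimentGrid) -> RejectionSummary:
    """ME test vs time-rescaling KS test on binned gamma renewal trains.

    For each gamma shape and sample count n, two independent trains of
    duration n·bin are simulated per replication; counts in consecutive bins
    form the pair sample for the ME test, while the KS test checks each
    train's rescaled interspike intervals (its rejection fraction averages
    over the two trains).
    """
    rows = []
    bin_s = grid.bin_ms / 1000.0
    cell = 0
    for n in grid.n_values:
        duration = n * bin_s
        for gamma in grid.gamma_values:
            ss = _cell_seed(grid.base_seed, cell)
            cell += 1
            spec = GammaProcessSpec(grid.rate_hz, gamma)
            rej_me = 0
            ks_checks = 0
            ks_rej = 0
            for rep_ss in ss.spawn(grid.replications):
                t_seed1, t_seed2, test_seed = rep_ss.spawn(3)
                tr1 = simulate_gamma_train(spec, duration,
                                           np.random.default_rng(t_seed1))
                tr2 = simulate_gamma_train(spec, duration,
                                           np.random.default_rng(t_seed2))
                c1 = bin_counts(tr1, bin_s)[:n]
                c2 = bin_counts(tr2, bin_s)[:n]
                data = CountPairSample(c1, c2)
                res = run_test(data, ENTROPY_DIFF, grid.alpha, grid.n_mc,
                               grid.anneal_config(test_seed))
                rej_me += res.rejected
                for tr in (tr1, tr2):
                    if tr.n_spikes >= 2:
                        rate_hat = tr.n_spikes / duration
                        n_bins = int(duration / bin_s)
                        p_ks = time_rescaling_ks(
                            tr, np.full(n_bins, rate_hat), bin_s)
                        ks_checks += 1
                        ks_rej += p_ks < grid.alpha
            rows.append({"test": "mc_maxent", "gamma": gamma, "n": n,
                         "n_rejected": rej_me,
                         "replications": grid.replications})
            rows.append({"test": "time_rescaling_ks", "gamma": gamma, "n": n,
                         "n_rejected": ks_rej, "replications": ks_checks})
    return _summarize(rows, {"experiment": "autocorrelation",
                             "grid": repr(grid)})


def run_dataset_scan(df: pd.DataFrame, grid: ExperimentGrid,
                     divergence_name: str = "entropy_diff"
                     ) -> RejectionSummary:
    """Scan a tidy count dataset: one test per design cell, FDR per bin size.

    Expects the fixture frame layout (columns pair, condition, orientation,
    bin_ms, x, y[, trial]).  With the entropy-difference statistic one test
    runs per (pair, condition, orientation); with the mutual-information
    statistic orientations form the stimulus ensemble, so one labelled test
    runs per (pair, condition).  Benjamini–Hochberg correction is applied
    within each (bin size, condition) universe and never across bin sizes,
    since each bin size carries a separate hypothesis.
    """
    divergence = get_divergence(divergence_name)
    required = {"pair", "condition", "orientation", "bin_ms", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset missing columns {sorted(missing)}")
    rows = []
    cell = 0
    for bin_ms, df_bin in df.groupby("bin_ms"):
        for cond, df_cond in df_bin.groupby("condition"):
            ps = []
            if divergence.needs_labels:
                groups = df_cond.groupby("pair")
            else:
                groups = df_cond.groupby(["pair", "orientation"])
            for _, g in groups:
                ss = _cell_seed(grid.base_seed, cell)
                cell += 1
                labels = (g["orientation"].to_numpy()
                          if divergence.needs_labels else None)
                data = CountPairSample(g["x"].to_numpy(), g["y"].to_numpy(),
                                       labels)
                res = run_test(data, divergence, grid.alpha, grid.n_mc,
                               grid.anneal_config(ss))
                ps.append(res.p_value)
            fdr = bh_procedure(np.asarray(ps), grid.alpha)
            rows.append({"bin_ms": bin_ms, "condition": cond,
                         "n_rejected": fdr.n_rejected,
                         "replications": len(ps)})
    return _summarize(rows, {"experiment": "dataset_scan",
                             "divergence": divergence_name,
                             "grid": repr(grid)})
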