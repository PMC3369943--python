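"""Gamma renewal spike trains, binning, and synthetic experiment fixtures.

Interspike intervals are i.i.d. Gamma(shape, scale = 1 / (shape · rate)), so
the mean interval is 1/rate regardless of the shape parameter.  Shape 1
recovers the Poisson process; shape > 1 adds a refractory period and makes
the train more regular (ISI coefficient of variation 1/sqrt(shape)), which
induces autocorrelation in binned counts.

The fixture generator emulates a multielectrode adaptation experiment:
11 simultaneously recorded neurons (55 pairs) split into high and low
firing-rate subpopulations, 8 stimulus orientations, control and adaptation
conditions, 42 trials per design cell, with a configurable bivariate
dependence model per pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .generators import build_mixture_model
from .maxent import MarginalSpec, fit_maxent, sample, truncate_support

__all__ = [
    "SpikeTrain",
    "GammaProcessSpec",
    "ExperimentFixture",
    "simulate_gamma_train",
    "bin_counts",
    "generate_fixture",
    "read_spike_trains",
    "write_spike_trains",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (seconds) within [0, duration]."""

    times: np.ndarray
    duration: float

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size and ((times < 0).any() or (times > self.duration).any()):
            raise InvalidParameterError("spike times must lie in [0, duration]")
        if times.size > 1 and (np.diff(times) <= 0).any():
            raise InvalidParameterError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class GammaProcessSpec:
    """Renewal process with Gamma ISIs: rate in Hz, shape >= 1."""

    rate_hz: float
    shape: float = 1.0

    def __post_init__(self):
        if self.rate_hz <= 0:
            raise InvalidParameterError("rate must be positive")
        if self.shape < 1.0:
            raise InvalidParameterError("shape < 1 is not supported")


def simulate_gamma_train(spec: GammaProcessSpec, duration_s: float,
                         seed: int | np.random.Generator | None = None
                         ) -> SpikeTrain:
    """Ordinary renewal process: cumulative Gamma ISIs from t = 0."""
    if duration_s <= 0:
        raise InvalidParameterError("duration must be positive")
    rng = np.random.default_rng(seed)
    scale = 1.0 / (spec.shape * spec.rate_hz)
    times = []
    t = 0.0
    # draw in blocks sized to overshoot the duration with margin
    block = max(16, int(duration_s * spec.rate_hz * 1.5) + 8)
    while t <= duration_s:
        isis = rng.gamma(spec.shape, scale, size=block)
        cum = t + np.cumsum(isis)
        times.append(cum)
        t = cum[-1]
    times = np.concatenate(times)
    return SpikeTrain(times[times <= duration_s], duration_s)


def bin_counts(train: SpikeTrain, bin_s: float) -> np.ndarray:
    """Spike counts in consecutive [k·bin, (k+1)·bin) windows.

    The trailing partial bin is discarded.
    """
    if bin_s <= 0:
        raise InvalidParameterError("bin width must be positive")
    n_bins = int(np.floor(train.duration / bin_s + 1e-12))
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(train.times, bins=edges)
    return counts.astype(np.int64)


def read_spike_trains(path: str | Path, duration: float) -> list[SpikeTrain]:
    """One line per trial: space-separated spike times in seconds."""
    trains = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        times = np.array([float(tok) for tok in line.split()])
        trains.append(SpikeTrain(times, duration))
    return trains


def write_spike_trains(trains: Sequence[SpikeTrain], path: str | Path) -> None:
    lines = [" ".join(f"{t:.6f}" for t in tr.times) for tr in trains]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# experiment fixture


@dataclass(frozen=True)
class ExperimentFixture:
    """Design of a synthetic multielectrode adaptation experiment."""

    n_neurons: int = 11
    conditions: tuple[str, ...] = ("control", "adaptation")
    orientations: tuple = (0, 22, 45, 67, 90, 112, 135, 157)
    repetitions: int = 42
    bin_sizes_ms: tuple[int, ...] = (10, 20, 40, 80, 100, 200, 400)
    dependence: str = "independent"           # independent | maxent | M1 | M2
    dependence_param: float = 0.0             # rho for maxent, m for M1/M2
    high_rate_range_hz: tuple[float, float] = (20.0, 35.0)
    low_rate_range_hz: tuple[float, float] = (2.0, 8.0)
    high_fraction: float = 0.5

    def __post_init__(self):
        if self.repetitions < 1:
            raise InvalidParameterError("repetitions must be >= 1")
        if self.dependence not in {"independent", "maxent", "M1", "M2"}:
            raise InvalidParameterError(f"unknown dependence {self.dependence!r}")

    @property
    def n_pairs(self) -> int:
        return self.n_neurons * (self.n_neurons - 1) // 2

    def draw_rates_hz(self, rng: np.random.Generator) -> np.ndarray:
        """Bimodal per-neuron rates: high and low firing-rate populations."""
        n_high = int(round(self.high_fraction * self.n_neurons))
        high = rng.uniform(*self.high_rate_range_hz, size=n_high)
        low = rng.uniform(*self.low_rate_range_hz, size=self.n_neurons - n_high)
        rates = np.concatenate([high, low])
        rng.shuffle(rates)
        return rates


def _pair_table(fix: ExperimentFixture, rate_x: float, rate_y: float):
    """Bivariate count table for one pair at given per-bin expected counts."""
    if fix.dependence == "independent":
        mx, my = MarginalSpec(rate_x), MarginalSpec(rate_y)
        return fit_maxent(mx, my, 0.0, truncate_support(mx, my)).pmf
    if fix.dependence == "maxent":
        mx, my = MarginalSpec(rate_x), MarginalSpec(rate_y)
        return fit_maxent(mx, my, fix.dependence_param,
                          truncate_support(mx, my)).pmf
    # copula mixture families share one rate by construction
    rate = 0.5 * (rate_x + rate_y)
    return build_mixture_model(fix.dependence, fix.dependence_param, rate).pmf


def generate_fixture(fix: ExperimentFixture,
                     seed: int | np.random.Generator | None = None,
                     metadata_path: str | Path | None = None) -> pd.DataFrame:
    """Draw the full labelled count dataset for the fixture design.

    Returns a tidy frame with columns (pair, neuron_i, neuron_j, condition,
    orientation, bin_ms, trial, x, y); one row per trial and design cell.
    """
    rng = np.random.default_rng(seed)
    rates_hz = fix.draw_rates_hz(rng)
    pairs = [(i, j) for i in range(fix.n_neurons)
             for j in range(i + 1, fix.n_neurons)]
    records = []
    for bin_ms in fix.bin_sizes_ms:
        bin_s = bin_ms / 1000.0
        for cond in fix.conditions:
            for orient in fix.orientations:
                for p_idx, (i, j) in enumerate(pairs):
                    rx = max(rates_hz[i] * bin_s, 1e-2)
                    ry = max(rates_hz[j] * bin_s, 1e-2)
                    table = _pair_table(fix, rx, ry)
                    s = sample(table, fix.repetitions, rng)
                    for trial in range(fix.repetitions):
                        records.append((p_idx, i, j, cond, orient, bin_ms,
                                        trial, s.xs[trial], s.ys[trial]))
    df = pd.DataFrame(records, columns=["pair", "neuron_i", "neuron_j",
                                        "condition", "orientation", "bin_ms",
                                        "trial", "x", "y"])
    if metadata_path is not None:
        meta = {
            "n_neurons": fix.n_neurons, "n_pairs": fix.n_pairs,
            "conditions": list(fix.conditions),
            "orientations": list(fix.orientations),
            "repetitions": fix.repetitions,
            "bin_sizes_ms": list(fix.bin_sizes_ms),
            "dependence": fix.dependence,
            "dependence_param": fix.dependence_param,
            "rates_hz": rates_hz.tolist(),
        }
        Path(metadata_path).write_text(json.dumps(meta, indent=2))
    return df
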