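"""Divergence statistics comparing empirical and reference count tables.

Two measures ship with the package, both in bits:

* ``entropy_diff`` — absolute difference of the Shannon entropies of the
  empirical table and the reference table.  Because the statistic is a
  difference of two plug-in entropies, any additive estimation bias common to
  both cancels under the null.
* ``mi_diff`` — absolute difference of the stimulus/response mutual
  informations, computed with a flat stimulus prior from per-stimulus
  conditional tables.  Used when trials carry stimulus labels.

Both are nonnegative and vanish when the two tables coincide.  The interface
accepts arbitrary user-supplied statistics of the same signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .data import CountPairSample
from .errors import InvalidParameterError, LabelingError
from .maxent import TruncatedBivariatePMF, TruncatedSupport, entropy

__all__ = [
    "EmpiricalPMF",
    "StimulusEnsemble",
    "DivergenceMeasure",
    "ENTROPY_DIFF",
    "MI_DIFF",
    "get_divergence",
    "empirical_pmf",
    "entropy_difference",
    "mutual_information",
    "mi_difference",
]

_LOG2 = np.log(2.0)


class EmpiricalPMF(TruncatedBivariatePMF):
    """Counts-of-counts table: entry (i, j) = #{pairs equal to (i, j)} / n."""

    __slots__ = ("n_obs",)

    def __init__(self, support: TruncatedSupport, probs: np.ndarray, n_obs: int):
        super().__init__(support, probs, _validate=False)
        self.n_obs = n_obs


def empirical_pmf(s: CountPairSample, support: TruncatedSupport) -> EmpiricalPMF:
    """Histogram of the sample on ``support``, expanded if counts overflow it."""
    need = TruncatedSupport(max(support.max_count_x, int(s.xs.max())),
                            max(support.max_count_y, int(s.ys.max())))
    table = np.zeros(need.shape)
    np.add.at(table, (s.xs, s.ys), 1.0)
    return EmpiricalPMF(need, table / s.n, s.n)


def entropy_difference(p_data: TruncatedBivariatePMF,
                       p_ref: TruncatedBivariatePMF) -> float:
    """|H(data) - H(reference)| in bits."""
    return abs(entropy(p_data) - entropy(p_ref))


@dataclass(frozen=True)
class StimulusEnsemble:
    """Per-stimulus conditional count tables plus a stimulus prior."""

    stimuli: tuple
    conditional_refs: tuple[TruncatedBivariatePMF, ...]
    prior: np.ndarray | None = None

    def __post_init__(self):
        if len(self.stimuli) != len(self.conditional_refs):
            raise InvalidParameterError("one conditional table per stimulus required")
        if len(self.stimuli) < 2:
            raise InvalidParameterError("mutual information needs >= 2 stimuli")
        prior = (np.full(len(self.stimuli), 1.0 / len(self.stimuli))
                 if self.prior is None else np.asarray(self.prior, dtype=float))
        if prior.size != len(self.stimuli) or not np.isclose(prior.sum(), 1.0):
            raise InvalidParameterError("prior must sum to 1 over the stimuli")
        # pad all conditionals onto a common grid
        sup = self.conditional_refs[0].support
        for c in self.conditional_refs[1:]:
            sup = sup.union(c.support)
        object.__setattr__(self, "conditional_refs",
                           tuple(c.expand(sup) for c in self.conditional_refs))
        object.__setattr__(self, "prior", prior)
        object.__setattr__(self, "stimuli", tuple(self.stimuli))

    @property
    def support(self) -> TruncatedSupport:
        return self.conditional_refs[0].support

    def index_of(self, label) -> int:
        try:
            return self.stimuli.index(label)
        except ValueError:
            raise LabelingError(f"stimulus {label!r} not in ensemble") from None


def mutual_information(ensemble: StimulusEnsemble) -> float:
    """I(S; (X, Y)) in bits for the ensemble's conditionals under its prior."""
    conds = np.stack([c.probs for c in ensemble.conditional_refs])
    prior = ensemble.prior[:, None, None]
    mix = (prior * conds).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(conds > 0, conds / np.where(mix > 0, mix, 1.0), 1.0)
        terms = prior * conds * np.log(ratio)
    return float(terms.sum() / _LOG2)


def mi_difference(data: CountPairSample, refs: StimulusEnsemble) -> float:
    """|I_empirical - I_reference| in bits, flat prior over the ensemble."""
    if data.stimulus_labels is None:
        raise LabelingError("mi_diff requires a stimulus-labelled sample")
    per_stim = data.by_stimulus()
    for lab in per_stim:
        refs.index_of(lab)
    sup = refs.support
    emp_conds = []
    for lab in refs.stimuli:
        if lab not in per_stim:
            raise LabelingError(f"no trials observed for stimulus {lab!r}")
        e = empirical_pmf(per_stim[lab], sup)
        emp_conds.append(e)
    # common grid across empirical conditionals (data may exceed ref support)
    emp_ens = StimulusEnsemble(refs.stimuli, tuple(emp_conds), refs.prior)
    return abs(mutual_information(emp_ens) - mutual_information(refs))


@dataclass(frozen=True)
class DivergenceMeasure:
    """Named, pluggable test statistic D(data table(s) ‖ reference table(s)).

    ``pair_stat`` is used for unlabelled data (single reference table);
    ``ensemble_stat`` for stimulus-labelled data (per-stimulus references).
    """

    name: str
    pair_stat: Callable[[TruncatedBivariatePMF, TruncatedBivariatePMF], float] | None = None
    ensemble_stat: Callable[[CountPairSample, StimulusEnsemble], float] | None = None

    @property
    def needs_labels(self) -> bool:
        return self.pair_stat is None

    def __call__(self, *args):
        fn = self.ensemble_stat if self.needs_labels else self.pair_stat
        return fn(*args)


ENTROPY_DIFF = DivergenceMeasure("entropy_diff", pair_stat=entropy_difference)
MI_DIFF = DivergenceMeasure("mi_diff", ensemble_stat=mi_difference)

_REGISTRY: Mapping[str, DivergenceMeasure] = {
    "entropy_diff": ENTROPY_DIFF,
    "mi_diff": MI_DIFF,
}


def get_divergence(name: str) -> DivergenceMeasure:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown divergence {name!r}; choose from {sorted(_REGISTRY)}"
        ) from None
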