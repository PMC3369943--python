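"""Divergence statistics: empirical tables, entropy and MI differences."""

import numpy as np
import pytest

from spikemaxent import (
    CountPairSample,
    LabelingError,
    MarginalSpec,
    StimulusEnsemble,
    TruncatedBivariatePMF,
    TruncatedSupport,
    empirical_pmf,
    entropy_difference,
    fit_maxent,
    mi_difference,
    mutual_information,
    sample,
    truncate_support,
)


class TestEmpiricalPMF:
    def test_mass_placement(self):
        s = CountPairSample.from_pairs([(0, 0), (0, 0), (1, 2), (1, 2)])
        emp = empirical_pmf(s, TruncatedSupport(2, 2))
        assert emp.probs[0, 0] == 0.5
        assert emp.probs[1, 2] == 0.5
        assert emp.probs.sum() == 1.0

    def test_single_observation(self):
        emp = empirical_pmf(CountPairSample.from_pairs([(3, 1)]),
                            TruncatedSupport(4, 4))
        assert emp.probs[3, 1] == 1.0

    def test_frequencies_are_integer_multiples(self, rng):
        s = CountPairSample(rng.poisson(3, 40), rng.poisson(3, 40))
        emp = empirical_pmf(s, TruncatedSupport(10, 10))
        np.testing.assert_allclose((emp.probs * 40) % 1.0, 0.0, atol=1e-9)

    def test_support_expands_to_cover_data(self):
        s = CountPairSample.from_pairs([(15, 0)])
        emp = empirical_pmf(s, TruncatedSupport(3, 3))
        assert emp.support.max_count_x >= 15


class TestEntropyDifference:
    def test_zero_on_identical_tables(self, me_rho02):
        assert entropy_difference(me_rho02.pmf, me_rho02.pmf) == 0.0

    def test_uniform_vs_point_mass(self):
        sup = TruncatedSupport(1, 1)
        uniform = TruncatedBivariatePMF(sup, np.full((2, 2), 0.25))
        point = np.zeros((2, 2))
        point[0, 0] = 1.0
        point = TruncatedBivariatePMF(sup, point)
        assert entropy_difference(uniform, point) == pytest.approx(2.0)

    def test_matches_direct_summation_oracle(self, me_rho02):
        data = sample(me_rho02.pmf, 200, seed=11)
        emp = empirical_pmf(data, me_rho02.pmf.support)
        stat = entropy_difference(emp, me_rho02.pmf)
        # independent plug-in computation from raw counts
        _, counts = np.unique(np.column_stack([data.xs, data.ys]), axis=0,
                              return_counts=True)
        f = counts / 200
        h_emp = float(-(f * np.log2(f)).sum())
        p = me_rho02.pmf.probs
        h_ref = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
        assert stat == pytest.approx(abs(h_emp - h_ref), abs=1e-12)


def _me_ensemble(rates, rho=0.1):
    tabs = []
    sup = None
    for rx in rates:
        mx, my = MarginalSpec(rx), MarginalSpec(2.0)
        tabs.append(fit_maxent(mx, my, rho, truncate_support(mx, my)).pmf)
    return StimulusEnsemble(tuple(range(len(rates))), tuple(tabs))


class TestMutualInformation:
    def test_identical_conditionals_zero(self, me_rho02):
        ens = StimulusEnsemble((0, 1), (me_rho02.pmf, me_rho02.pmf))
        assert mutual_information(ens) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_conditionals_one_bit(self):
        sup = TruncatedSupport(1, 1)
        a = np.zeros((2, 2))
        a[0, 0] = 1.0
        b = np.zeros((2, 2))
        b[1, 1] = 1.0
        ens = StimulusEnsemble((0, 1), (TruncatedBivariatePMF(sup, a),
                                        TruncatedBivariatePMF(sup, b)))
        assert mutual_information(ens) == pytest.approx(1.0)

    def test_matches_double_sum_oracle(self):
        ens = _me_ensemble([1.0, 2.0, 3.0, 4.0, 5.0, 1.5, 2.5, 3.5])
        expected = 0.0
        prior = 1.0 / len(ens.stimuli)
        mix = sum(prior * c.probs for c in ens.conditional_refs)
        for c in ens.conditional_refs:
            mask = c.probs > 0
            expected += prior * float(
                (c.probs[mask] * np.log2(c.probs[mask] / mix[mask])).sum())
        assert mutual_information(ens) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_stimulus_entropy(self):
        ens = _me_ensemble([1.0, 5.0, 2.0, 4.0])
        mi = mutual_information(ens)
        assert 0.0 <= mi <= 2.0


class TestMIDifference:
    def test_zero_when_refs_equal_empirical(self, rng):
        xs = rng.poisson(3, 60)
        ys = rng.poisson(3, 60)
        labels = np.repeat([0, 1], 30)
        data = CountPairSample(xs, ys, labels)
        sup = TruncatedSupport(int(xs.max()), int(ys.max()))
        conds = tuple(empirical_pmf(sub, sup)
                      for _, sub in sorted(data.by_stimulus().items()))
        refs = StimulusEnsemble((0, 1), conds)
        assert mi_difference(data, refs) == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_empirical_mi_for_flat_reference(self, me_rho02, rng):
        labels = np.repeat([0, 1], 40)
        s0 = sample(me_rho02.pmf, 40, rng)
        s1 = sample(me_rho02.pmf, 40, rng)
        data = CountPairSample(np.concatenate([s0.xs, s1.xs]),
                               np.concatenate([s0.ys, s1.ys]), labels)
        refs = StimulusEnsemble((0, 1), (me_rho02.pmf, me_rho02.pmf))
        # reference MI is zero, so the statistic equals the empirical MI
        sup = refs.support
        conds = tuple(empirical_pmf(sub, sup)
                      for _, sub in sorted(data.by_stimulus().items()))
        emp_mi = mutual_information(StimulusEnsemble((0, 1), conds))
        assert mi_difference(data, refs) == pytest.approx(emp_mi, abs=1e-12)

    def test_label_mismatch_raises(self, me_rho02):
        data = CountPairSample(np.array([1, 2]), np.array([0, 1]),
                               np.array(["a", "b"]))
        refs = StimulusEnsemble(("a", "c"), (me_rho02.pmf, me_rho02.pmf))
        with pytest.raises(LabelingError):
            mi_difference(data, refs)

    def test_unlabelled_data_raises(self, me_rho02):
        data = CountPairSample(np.array([1, 2]), np.array([0, 1]))
        refs = StimulusEnsemble((0, 1), (me_rho02.pmf, me_rho02.pmf))
        with pytest.raises(LabelingError):
            mi_difference(data, refs)
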