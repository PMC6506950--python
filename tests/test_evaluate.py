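import numpy as np
import pandas as pd
import pytest

from dmbench.evaluate import (
    Confusion,
    bh_adjust,
    classify,
    compute_metrics,
    consensus_overlap,
    sample_skewness,
    summarize_benchmark,
)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_hand_step_up(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_q_dominates_p(self, rng):
        p = rng.random(200)
        q = bh_adjust(p)
        assert np.all(q >= p) and np.all(q <= 1)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestClassify:
    def test_direct_application(self):
        c = classify(np.array([0.01, 0.2]), np.array([1, 1]))
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 0, 0)

    def test_boundary_q_not_significant(self):
        c = classify(np.array([0.05]), np.array([1]))
        assert c.tp == 0 and c.fn == 1

    def test_global_null(self):
        c = classify(np.array([0.01, 0.04, 0.5]), np.zeros(3))
        assert c.tp == 0 and c.fp == 2

    def test_margins_match_truth(self, rng):
        q = rng.random(100)
        eta = rng.integers(0, 2, 100)
        c = classify(q, eta)
        assert c.n_tested == 100
        assert c.tp + c.fn == (eta == 1).sum()
        assert c.fp + c.tn == (eta == 0).sum()


class TestMetrics:
    def test_hand_rates(self):
        m = compute_metrics(Confusion(tp=3, fp=1, tn=5, fn=1))
        assert m.tpr == pytest.approx(0.75)
        assert m.fpr == pytest.approx(1 / 6)
        assert m.error_probability == pytest.approx(0.25)

    def test_no_false_calls(self):
        m = compute_metrics(Confusion(tp=4, fp=0, tn=5, fn=1))
        assert m.error_probability == 0.0

    def test_no_calls_is_undefined_not_zero(self):
        m = compute_metrics(Confusion(tp=0, fp=0, tn=5, fn=5))
        assert np.isnan(m.error_probability)


class TestConsensusOverlap:
    def _table(self, sets, universe):
        rows = []
        for m, sig in sets.items():
            for o in universe:
                rows.append(dict(otu_id=o, method=m,
                                 qvalue=0.01 if o in sig else 0.5))
        return pd.DataFrame(rows)

    def test_hand_set_algebra(self):
        sets = {"poisson": {1, 2, 3}, "negbin": {2, 3}, "voom_lm": {2, 4}, "zig": {2}}
        res = self._table(sets, universe=range(1, 6))
        out = consensus_overlap(res)
        assert out["overlap"] == {2}
        assert out["unique_counts"] == {"poisson": 1, "negbin": 0, "voom_lm": 1, "zig": 0}
        assert out["pairwise_counts"][("poisson", "negbin")] == 2

    def test_identical_sets(self):
        sets = {m: {1, 2} for m in ("poisson", "negbin", "voom_lm", "zig")}
        out = consensus_overlap(self._table(sets, range(1, 4)))
        assert out["overlap"] == {1, 2}
        assert all(v == 0 for v in out["unique_counts"].values())

    def test_disjoint_sets(self):
        sets = {"poisson": {1}, "negbin": {2}, "voom_lm": {3}, "zig": {4}}
        out = consensus_overlap(self._table(sets, range(1, 6)))
        assert out["overlap"] == set()
        assert all(v == 1 for v in out["unique_counts"].values())

    def test_overlap_confusion_against_truth(self):
        sets = {m: {1, 2} for m in ("poisson", "negbin", "voom_lm", "zig")}
        truth = {1: 1, 2: 0, 3: 1}
        out = consensus_overlap(self._table(sets, range(1, 4)), truth=truth)
        c = out["overlap_confusion"]
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 0, 1)

    def test_missing_method_rejected(self):
        sets = {"poisson": {1}}
        with pytest.raises(ValueError):
            consensus_overlap(self._table(sets, range(1, 3)))


class TestSkewness:
    def test_symmetric_vector_zero(self):
        assert sample_skewness(np.array([-1.0, 0.0, 1.0])) == pytest.approx(0.0)

    def test_hand_adjusted_value(self):
        assert sample_skewness(np.array([0.0, 0.0, 0.0, 1.0])) == pytest.approx(2.0)

    def test_antisymmetry(self, rng):
        x = rng.exponential(size=500)
        assert sample_skewness(-x) == pytest.approx(-sample_skewness(x))

    def test_constant_vector_undefined(self):
        assert np.isnan(sample_skewness(np.full(10, 3.0)))


class TestSummarize:
    def _per_sim(self, errs_by_method):
        rows = []
        for m, errs in errs_by_method.items():
            for s, e in enumerate(errs):
                rows.append(dict(simulation_id=s, method=m, tpr=0.5, fpr=0.1,
                                 error_probability=e, skewness=0.0))
        return pd.DataFrame(rows)

    def test_single_simulation_medians(self):
        out = summarize_benchmark(self._per_sim({"poisson": [0.3], "negbin": [0.1]}))
        assert out.medians.loc["poisson", "error_probability"] == pytest.approx(0.3)

    def test_median_over_three(self):
        out = summarize_benchmark(self._per_sim({"negbin": [0.1, 0.2, 0.3]}))
        assert out.medians.loc["negbin", "error_probability"] == pytest.approx(0.2)

    def test_lowest_error_counts(self):
        out = summarize_benchmark(self._per_sim({"poisson": [0.1, 0.4],
                                                 "negbin": [0.2, 0.3]}))
        assert out.lowest_error_counts == {"poisson": 1, "negbin": 1}

    def test_ties_credit_nobody(self):
        out = summarize_benchmark(self._per_sim({"poisson": [0.2], "negbin": [0.2]}))
        assert out.lowest_error_counts == {"poisson": 0, "negbin": 0}

    def test_undefined_errors_excluded(self):
        out = summarize_benchmark(
            self._per_sim({"poisson": [np.nan, 0.2, 0.04]})
        )
        assert out.medians.loc["poisson", "error_probability"] == pytest.approx(0.12)
        assert out.frac_error_below["poisson"] == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_benchmark(pd.DataFrame())
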