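import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from streampcb.rcc_stats import (
    CompositeSample, RCCSpec, decline_test, rcc_test, substitute_nondetects,
    summarize)


class TestNondetects:
    def test_half_mdl_substitution(self):
        out = substitute_nondetects([0.0, 0.42], [False, True], [0.10, 0.10])
        assert out[0] == pytest.approx(0.05)
        assert out[1] == pytest.approx(0.42)

    def test_all_nondetect_mean(self):
        out = substitute_nondetects([0, 0, 0], [False] * 3, 1.0)
        assert out.mean() == pytest.approx(0.5)

    def test_nondetect_without_mdl_rejected(self):
        with pytest.raises(ValueError):
            substitute_nondetects([0.0], [False], [0.0])


class TestSummarize:
    def test_hand_arithmetic(self):
        s = summarize([2, 4, 6])
        assert s["mean"] == pytest.approx(4.0)
        assert s["sem"] == pytest.approx(1.1547, abs=1e-4)
        assert s["interval"][0] == pytest.approx(1.691, abs=1e-3)
        assert s["interval"][1] == pytest.approx(6.309, abs=1e-3)

    def test_identical_values_zero_sem(self):
        assert summarize([3, 3, 3, 3])["sem"] == 0.0

    def test_single_sample_interval_flagged(self):
        assert summarize([1.0])["undefined_interval"]

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(vals=st.lists(st.floats(0, 100), min_size=2, max_size=20),
           seed=st.integers(0, 1000))
    def test_permutation_invariance(self, vals, seed):
        rng = np.random.default_rng(seed)
        shuffled = rng.permutation(vals)
        a, b = summarize(vals), summarize(list(shuffled))
        assert a["mean"] == pytest.approx(b["mean"])
        assert a["sem"] == pytest.approx(b["sem"])

    def test_composite_bookkeeping(self):
        # 10 composite analyses of 3 fish each represent 30 fish
        samples = [CompositeSample("CBVP", "creek_chub", "2017-05-01", 1.0,
                                   n_fish=3) for _ in range(10)]
        assert len(samples) == 10
        assert sum(s.n_fish for s in samples) == 30


class TestRCCTest:
    def test_clear_success(self):
        spec = RCCSpec()
        d = rcc_test(np.array([1.0, 1.2, 0.8, 1.1, 0.9]), spec, "CBVP")
        assert d.outcome == "success"
        assert d.t_statistic == pytest.approx(-18.38, abs=0.01)
        assert d.p_below == pytest.approx(2.6e-5, rel=0.1)

    def test_mean_at_target_inconclusive(self):
        spec = RCCSpec()
        vals = np.array([2.0, 2.6, 2.3, 2.1, 2.5])  # mean exactly 2.3
        assert vals.mean() == pytest.approx(2.3)
        assert rcc_test(vals, spec, "CBVP").outcome == "inconclusive"

    def test_clear_failure(self):
        spec = RCCSpec()
        d = rcc_test(np.array([3.0, 3.1, 2.9, 3.2, 3.0]), spec, "CBVP")
        assert d.outcome == "failure"

    def test_basis_mismatch_refused(self):
        spec = RCCSpec()
        samples = [CompositeSample("RC43", "longear_sunfish", "2017-05-01",
                                   0.1, basis="whole_body") for _ in range(4)]
        with pytest.raises(ValueError, match="basis"):
            rcc_test(samples, spec, "RC43")

    def test_too_few_composites_rejected(self):
        with pytest.raises(ValueError):
            rcc_test(np.array([1.0, 1.1]), RCCSpec(), "CBVP")

    def test_matches_reference_implementation(self):
        # independent route: scipy's one-sample t-test on 1000 random sets
        rng = np.random.default_rng(42)
        spec = RCCSpec()
        target = spec.targets["CBVP"][0]
        for _ in range(1000):
            n = int(rng.integers(3, 25))
            mean = rng.uniform(0.2, 2 * target)
            sd = rng.uniform(0.05, 1.5)
            vals = rng.normal(mean, sd, n)
            vals = np.abs(vals)
            d = rcc_test(vals, spec, "CBVP")
            p_lo = stats.ttest_1samp(vals, target, alternative="less").pvalue
            p_hi = stats.ttest_1samp(vals, target, alternative="greater").pvalue
            if p_lo < spec.alpha:
                expected = "success"
            elif p_hi < spec.alpha:
                expected = "failure"
            else:
                expected = "inconclusive"
            assert d.outcome == expected
            assert d.p_below == pytest.approx(p_lo)


class TestDeclineTest:
    def test_identical_groups_p_half(self):
        g = np.array([1.0, 1.1, 0.9, 1.05])
        assert decline_test(g, g)["p"] == pytest.approx(0.5)

    def test_clear_decline_significant(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(5.0, 0.1, 10)
        post = rng.normal(1.0, 0.1, 10)
        assert decline_test(pre, post)["significant"]

    def test_swap_flips_one_sidedness(self):
        rng = np.random.default_rng(5)
        a = rng.normal(2.0, 0.5, 8)
        b = rng.normal(1.5, 0.5, 8)
        p1 = decline_test(a, b)["p"]
        p2 = decline_test(b, a)["p"]
        assert p1 + p2 == pytest.approx(1.0)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            decline_test([1.0], [1.0, 2.0])
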