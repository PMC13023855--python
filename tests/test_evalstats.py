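import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cemprep import evalstats as ev


def auroc_pair_oracle(y, s):
    """Exhaustive positive-negative pair enumeration."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert ev.auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_four_point_example(self):
        assert ev.auroc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.3]) == 0.75

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_pair_enumeration_with_ties(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 50))
        y = np.r_[1, 0, r.integers(0, 2, n - 2)]
        s = np.round(r.uniform(0, 1, n), 1)  # coarse grid forces ties
        assert ev.auroc(y, s) == pytest.approx(auroc_pair_oracle(y, s))

    def test_permutation_null_centers_at_half(self, rng):
        n = 40
        s = rng.uniform(0, 1, n)
        vals = []
        for _ in range(1000):
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=n // 2, replace=False)] = 1
            vals.append(ev.auroc(y, s))
        assert abs(np.mean(vals) - 0.5) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.auroc([1, 1], [0.1, 0.2])


def auprc_sweep_oracle(y, s):
    """Exhaustive threshold sweep for average precision."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    thresholds = np.sort(np.unique(s))[::-1]
    prev_recall, total = 0.0, 0.0
    for t in thresholds:
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        precision = tp / pred.sum()
        recall = tp / (y == 1).sum()
        total += (recall - prev_recall) * precision
        prev_recall = recall
    return total


class TestAuprc:
    def test_perfect_ranking(self):
        assert ev.auprc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_single_tied_score_equals_prevalence(self):
        y = [1, 0, 0, 0, 1]
        assert ev.auprc(y, [0.5] * 5) == pytest.approx(2 / 5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_sweep_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 40))
        y = np.r_[1, 0, r.integers(0, 2, n - 2)]
        s = np.round(r.uniform(0, 1, n), 1)
        assert ev.auprc(y, s) == pytest.approx(auprc_sweep_oracle(y, s))


class TestYouden:
    def test_separable_returns_lowest_positive_score(self):
        y = [0, 0, 1, 1]
        s = [0.1, 0.3, 0.6, 0.9]
        assert ev.youden_threshold(y, s) == 0.6

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_j_at_threshold_equals_exhaustive_max(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 40))
        y = np.r_[1, 0, r.integers(0, 2, n - 2)]
        s = np.round(r.uniform(0, 1, n), 1)
        t = ev.youden_threshold(y, s)

        def j_at(th):
            pred = np.asarray(s) >= th
            sens = (pred & (y == 1)).sum() / (y == 1).sum()
            spec = (~pred & (y == 0)).sum() / (y == 0).sum()
            return sens + spec - 1.0

        # candidates: below, at, between and above every observed score
        candidates = np.concatenate([[-1.0], np.unique(s),
                                     np.unique(s) + 1e-6, [2.0]])
        assert j_at(t) == pytest.approx(max(j_at(c) for c in candidates))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.youden_threshold([1, 1, 1], [0.2, 0.3, 0.4])


class TestConfusionReport:
    def test_forced_arithmetic_case(self):
        y = [1] * 10 + [0] * 10
        s = [0.9] * 6 + [0.1] * 4 + [0.8] * 2 + [0.2] * 8
        rep = ev.confusion_report(y, s, threshold=0.5)
        assert rep.recall_malignant == pytest.approx(0.6)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.balanced_accuracy == pytest.approx(0.7)
        assert rep.accuracy == pytest.approx(0.7)

    def test_threshold_limits(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.uniform(0.1, 0.9, 30)
        low = ev.confusion_report(y, s, threshold=0.0)
        assert low.recall_malignant == 1.0 and low.specificity == 0.0
        high = ev.confusion_report(y, s, threshold=1.1)
        assert high.recall_malignant == 0.0 and high.specificity == 1.0

    def test_balanced_accuracy_identity_exact(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 25)
            y[:2] = [0, 1]
            s = rng.uniform(0, 1, 25)
            rep = ev.confusion_report(y, s, rng.uniform(0, 1))
            assert rep.balanced_accuracy == (rep.recall_malignant + rep.specificity) / 2


class TestDeLong:
    def test_identical_scores_give_p_one(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.uniform(0, 1, 30)
        res = ev.delong_test(y, s, s)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_antisymmetry(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        a = rng.uniform(0, 1, 60)
        b = np.clip(y * 0.3 + rng.uniform(0, 0.7, 60), 0, 1)
        ab = ev.delong_test(y, a, b)
        ba = ev.delong_test(y, b, a)
        assert ab.statistic == pytest.approx(-ba.statistic)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_mismatched_case_sets_rejected(self):
        with pytest.raises(ValueError):
            ev.delong_test([0, 1], [0.1, 0.9], [0.1, 0.9, 0.5])

    def test_single_auc_variance_matches_bootstrap(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        s = np.clip(0.4 * y + rng.uniform(0, 0.6, n), 0, 1)
        var = ev.delong_variance(y, s)
        boot = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) == 2:
                boot.append(ev.auroc(y[idx], s[idx]))
        assert var == pytest.approx(np.var(boot, ddof=1), rel=0.25)

    def test_independent_scorers_match_classical_variance_sum(self, rng):
        """With A and B independent, var(dAUC) ~ var(A) + var(B)."""
        n = 300
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        a = np.clip(0.3 * y + rng.uniform(0, 0.7, n), 0, 1)
        b = np.clip(0.3 * y + rng.uniform(0, 0.7, n), 0, 1)
        auc_a, v10a, v01a = ev._delong_components(y, a)
        auc_b, v10b, v01b = ev._delong_components(y, b)
        res = ev.delong_test(y, a, b)
        var_sum = ev.delong_variance(y, a) + ev.delong_variance(y, b)
        z_classical = (auc_a - auc_b) / np.sqrt(var_sum)
        assert res.statistic == pytest.approx(z_classical, rel=0.25, abs=0.3)


class TestMcNemar:
    def test_no_discordance_gives_p_one(self):
        res = ev.mcnemar_test([True, False] * 5, [True, False] * 5)
        assert res.p_value == 1.0

    def test_chi_square_formula_b13_c13(self):
        a = [True] * 13 + [False] * 13 + [True] * 10
        b = [False] * 13 + [True] * 13 + [True] * 10
        res = ev.mcnemar_test(a, b)
        assert res.statistic == pytest.approx(1 / 26)

    def test_chi_square_formula_b20_c5(self):
        a = [True] * 20 + [False] * 5
        b = [False] * 20 + [True] * 5
        res = ev.mcnemar_test(a, b)
        assert res.statistic == pytest.approx((15 - 1) ** 2 / 25)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(7.84, 1)))

    def test_exact_branch_matches_binomial_enumeration(self):
        a = [True] * 10 + [False] * 2
        b = [False] * 10 + [True] * 2
        res = ev.mcnemar_test(a, b)
        # doubled lower binomial tail over 12 discordant pairs
        from math import comb

        tail = sum(comb(12, k) for k in range(0, 3)) / 2**12
        assert res.p_value == pytest.approx(min(1.0, 2 * tail))


class TestWilcoxon:
    def test_all_positive_differences_exact_p(self):
        res = ev.wilcoxon_signed_rank([0.9, 0.8, 0.85, 0.7, 0.95],
                                      [0.6, 0.5, 0.65, 0.6, 0.7])
        assert res.p_value == pytest.approx(1 / 16)

    def test_identical_inputs_give_p_one(self):
        res = ev.wilcoxon_signed_rank([0.5] * 5, [0.5] * 5)
        assert res.p_value == 1.0

    def test_statistic_matches_sign_pattern_enumeration(self, rng):
        for _ in range(10):
            a = rng.uniform(0, 1, 5)
            b = rng.uniform(0, 1, 5)
            d = a - b
            d = d[d != 0]
            ranks = stats.rankdata(np.abs(d))
            w = ranks[d > 0].sum()
            dist = []
            for pattern in range(2 ** len(d)):
                signs = [(pattern >> i) & 1 for i in range(len(d))]
                dist.append(sum(r for r, s in zip(ranks, signs) if s))
            dist = np.asarray(dist)
            lo = np.mean(dist <= w + 1e-9)
            hi = np.mean(dist >= w - 1e-9)
            expected = min(1.0, 2 * min(lo, hi))
            res = ev.wilcoxon_signed_rank(a, b)
            assert res.statistic == pytest.approx(w)
            assert res.p_value == pytest.approx(expected)

    def test_matches_scipy_exact_when_no_ties(self, rng):
        a = rng.uniform(0, 1, 10)
        b = rng.uniform(0, 1, 10)
        ours = ev.wilcoxon_signed_rank(a, b)
        theirs = stats.wilcoxon(a, b, mode="exact", alternative="two-sided")
        assert ours.p_value == pytest.approx(theirs.pvalue)


class TestBootstrap:
    def _preds(self, y, s, patients=None):
        n = len(y)
        pats = patients if patients is not None else [f"P{i}" for i in range(n)]
        return ev.PredictionSet(np.arange(n).astype(str), np.asarray(pats),
                                np.asarray(s), np.asarray(y))

    def test_degenerate_metric_gives_point_ci(self):
        y = [1] * 5 + [0] * 5
        s = [1.0] * 5 + [0.0] * 5
        preds = self._preds(y, s)
        lo, hi = ev.bootstrap_ci(
            preds, lambda yy, ss: ev.confusion_report(yy, ss, 0.5).accuracy,
            n_boot=100, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_ci_contains_point_estimate(self, rng):
        for trial in range(20):
            n = 40
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            s = np.clip(0.4 * y + rng.uniform(0, 0.6, n), 0, 1)
            preds = self._preds(y, s)
            lo, hi = ev.bootstrap_ci(preds, ev.auroc, n_boot=200, seed=trial)
            point = ev.auroc(y, s)
            assert lo - 1e-9 <= point <= hi + 1e-9

    def test_patients_resampled_together(self, rng):
        # two images per patient with identical scores: patient-level
        # resampling must never split them (CI from 100 resamples of a
        # perfectly patient-clustered metric is exact)
        y = np.repeat([1, 1, 0, 0, 1, 0], 2)
        s = np.repeat([0.9, 0.8, 0.2, 0.1, 0.7, 0.3], 2)
        pats = np.repeat([f"P{i}" for i in range(6)], 2)
        preds = self._preds(y, s, pats)
        lo, hi = ev.bootstrap_ci(preds, ev.auroc, n_boot=100, seed=1)
        assert 0.0 <= lo <= hi <= 1.0
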