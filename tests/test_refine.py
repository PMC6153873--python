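"""Scheme refinement: ANOVA, t-tests, ROC-AUC and cutoff optimisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrspeaks import (
    RatioRuleModel, SimulationConfig, anova_oneway, optimal_cutoff,
    refine_scheme, roc_auc, sample_ratio_profiles, two_tailed_t,
)
from mrspeaks.simulate import LogNormalLevel

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def auc_bruteforce(scores, labels):
    """Pairwise-comparison AUC: P(positive > negative), ties half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def youden_bruteforce(scores, labels, direction):
    """Best sensitivity+specificity over every threshold between points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    unique = np.unique(scores)
    candidates = np.concatenate(
        ([-np.inf], (unique[:-1] + unique[1:]) / 2.0, [np.inf]))
    best = -1.0
    for t in candidates:
        predicted = scores > t if direction == "high" else scores < t
        sens = (predicted & labels).sum() / labels.sum()
        spec = (~predicted & ~labels).sum() / (~labels).sum()
        best = max(best, sens + spec)
    return best


scores_and_labels = st.lists(
    st.tuples(
        st.floats(min_value=-100, max_value=100,
                  allow_nan=False, allow_infinity=False),
        st.booleans(),
    ),
    min_size=4, max_size=50,
).filter(lambda items: 0 < sum(lab for _, lab in items) < len(items))


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

class TestAnova:
    def test_identical_groups(self):
        f, p = anova_oneway([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_three_group_case(self):
        """Groups {1,2,3},{11,12,13},{21,22,23}: between-group mean
        square 300, within 1, so F = 300."""
        f, p = anova_oneway([1, 2, 3], [11, 12, 13], [21, 22, 23])
        assert f == pytest.approx(300.0)
        assert p < 1e-4

    def test_p_decreases_with_separation(self):
        base = [1.0, 2.0, 3.0]
        previous = 1.1
        for shift in (0.0, 2.0, 5.0, 10.0):
            _, p = anova_oneway(base, base, [x + shift for x in base])
            assert p <= previous + 1e-12
            previous = p

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([1.0], [1, 2], [3, 4])


class TestWelchT:
    def test_identical_groups_give_p_one(self):
        assert two_tailed_t([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_textbook_value(self):
        """{1,2,3} vs {4,5,6}: t = 3.674, two-tailed p = 0.021 (df=4;
        pooled equals Welch here by symmetry)."""
        p = two_tailed_t([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.0213, abs=0.001)

    def test_symmetric_in_group_order(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 2, 7)
        assert two_tailed_t(a, b) == pytest.approx(two_tailed_t(b, a))

    def test_degenerate_equal_constants(self):
        assert two_tailed_t([2.0, 2.0], [2.0, 2.0]) == 1.0


class TestRocAuc:
    def test_perfect_separation(self):
        auc, direction = roc_auc([1, 2, 3, 10, 11, 12],
                                 [0, 0, 0, 1, 1, 1])
        assert auc == 1.0 and direction == "high"

    def test_identical_distributions_all_ties(self):
        auc, _ = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert auc == 0.5

    def test_interleaved_example(self):
        """Positives {2,4,6} vs negatives {1,3,5}: 6 of 9 pairs concordant."""
        auc, direction = roc_auc([2, 4, 6, 1, 3, 5], [1, 1, 1, 0, 0, 0])
        assert auc == pytest.approx(6 / 9)
        assert direction == "high"

    def test_low_direction_flag(self):
        auc, direction = roc_auc([1, 2, 3, 10, 11, 12],
                                 [1, 1, 1, 0, 0, 0])
        assert auc == 1.0 and direction == "low"

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(items=scores_and_labels)
    def test_matches_bruteforce_oracle(self, items):
        scores = [s for s, _ in items]
        labels = [lab for _, lab in items]
        auc, _ = roc_auc(scores, labels)
        oracle = auc_bruteforce(scores, labels)
        assert auc == pytest.approx(max(oracle, 1 - oracle), abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(items=scores_and_labels)
    def test_invariant_under_monotone_transform(self, items):
        # round to a coarse grid so exp() stays strictly monotone in floats
        scores = np.round(np.array([s for s, _ in items]), 3)
        labels = [lab for _, lab in items]
        auc, _ = roc_auc(scores, labels)
        transformed, _ = roc_auc(np.exp(scores / 50.0), labels)
        assert transformed == pytest.approx(auc, abs=1e-9)


class TestOptimalCutoff:
    def test_separated_groups_give_midpoint(self):
        result = optimal_cutoff([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert result.cutoff == pytest.approx(3.5)
        assert result.direction == "high"
        assert result.youden == pytest.approx(2.0)

    def test_identical_distributions_hit_sentinel(self):
        result = optimal_cutoff([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1],
                                direction="high")
        assert result.youden == pytest.approx(1.0)
        assert np.isinf(result.cutoff)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutoff([1, 2, 3], [0, 0, 0])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(items=scores_and_labels, direction=st.sampled_from(["high", "low"]))
    def test_matches_exhaustive_scan(self, items, direction):
        scores = [s for s, _ in items]
        labels = [lab for _, lab in items]
        result = optimal_cutoff(scores, labels, direction)
        oracle = youden_bruteforce(scores, labels, direction)
        assert result.youden == pytest.approx(oracle, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(items=scores_and_labels)
    def test_no_scanned_threshold_beats_returned_cutoff(self, items):
        scores = np.array([s for s, _ in items])
        labels = np.array([lab for _, lab in items])
        result = optimal_cutoff(scores, labels)
        n_pos, n_neg = labels.sum(), (~labels).sum()
        for t in np.concatenate(([-np.inf], np.unique(scores), [np.inf])):
            predicted = (scores > t if result.direction == "high"
                         else scores < t)
            j = ((predicted & labels).sum() / n_pos
                 + (~predicted & ~labels).sum() / n_neg)
            assert result.youden >= j - 1e-9


# ---------------------------------------------------------------------------
# Full refinement
# ---------------------------------------------------------------------------

def cohort(n_per_class, seed):
    config = SimulationConfig(
        class_counts={"PA": n_per_class, "EP": n_per_class, "MB": n_per_class})
    return sample_ratio_profiles(config, seed=seed)


class TestRefineScheme:
    def test_selects_generative_discriminators(self):
        report = refine_scheme(cohort(200, seed=101))
        assert sorted(report.step1_ratios) == ["mins_naa", "naa_cr"]
        assert report.step2_ratio == "mins_tcho"
        assert len(report.step2_checks) == 2

    def test_scheme_structure_matches_selection(self):
        report = refine_scheme(cohort(150, seed=55))
        step1, step2 = report.scheme.steps
        assert step1.label == "PA"
        assert {c.ratio for c in step1.conditions} == set(report.step1_ratios)
        assert step2.label == "MB"
        assert step2.conditions[0].ratio == report.step2_ratio
        assert report.scheme.else_class == "EP"

    def test_pure_noise_ratio_discarded_by_anova(self):
        """A ratio with an identical distribution in all three classes is
        dropped by the prefilter in at least 95% of repetitions; at the
        5% test level that is at least 34 of 40 seeds."""
        config = SimulationConfig(class_counts={"PA": 30, "EP": 30, "MB": 30})
        for levels in config.class_levels.values():
            levels["lmm09"] = LogNormalLevel(0.6, 0.3)
            levels["lmm13"] = LogNormalLevel(0.8, 0.3)
        discarded = 0
        for seed in range(40):
            table = sample_ratio_profiles(config, seed=seed)
            report = refine_scheme(table)
            if not report.anova.loc["lmm09_lmm13", "retained"]:
                discarded += 1
        assert discarded >= 34

    def test_row_permutation_invariance(self):
        table = cohort(60, seed=77)
        shuffled = table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = refine_scheme(table)
        b = refine_scheme(shuffled)
        assert a.step1_ratios == b.step1_ratios
        assert a.step2_ratio == b.step2_ratio
        assert {r: c.cutoff for r, c in a.step1_cutoffs.items()} == \
               {r: c.cutoff for r, c in b.step1_cutoffs.items()}

    def test_insufficient_class_counts_rejected(self):
        table = cohort(10, seed=1)
        table = table[table["true_class"] != "EP"]
        with pytest.raises(ValueError, match="at least"):
            RatioRuleModel(table)

    def test_cutoff_recovery_median_error_below_10pct(self):
        """Over 20 seeded 100-per-class cohorts the median relative error
        of the recovered step cutoffs against the generative crossing
        points (NAA/Cr 2.2, mIns/NAA 0.65, mIns/tCho 0.85) stays
        below 10%."""
        truth = {"naa_cr": 2.2, "mins_naa": 0.65, "mins_tcho": 0.85}
        errors = {name: [] for name in truth}
        for seed in range(20):
            report = refine_scheme(cohort(100, seed=300 + seed))
            for ratio, res in report.step1_cutoffs.items():
                if ratio in truth:
                    errors[ratio].append(
                        abs(res.cutoff - truth[ratio]) / truth[ratio])
            if report.step2_ratio in truth:
                errors[report.step2_ratio].append(
                    abs(report.step2_cutoff.cutoff - truth[report.step2_ratio])
                    / truth[report.step2_ratio])
        for ratio, errs in errors.items():
            assert len(errs) >= 15
            assert float(np.median(errs)) < 0.10


class TestModelResultsApi:
    def test_results_expose_estimates_and_summary(self):
        results = RatioRuleModel(cohort(80, seed=9)).fit()
        assert set(results.cutoffs) >= {"naa_cr", "mins_naa"}
        text = results.summary()
        assert "Selected scheme" in text
        assert "naa_cr" in text
        assert "overall" in text

    def test_scatter_data_carries_selected_axes(self):
        results = RatioRuleModel(cohort(80, seed=9)).fit()
        data = results.scatter_data()
        assert "true_class" in data.columns
        for ratio in results.report.step1_ratios:
            assert ratio in data.columns
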