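import numpy as np
import pandas as pd
import pytest
from scipy import stats

from molqtl.enrichment import (
    bh_adjust,
    binom_test_two_sided,
    fisher_2x2,
    glm_enrichment,
    permutation_enrichment,
    proportion_chisq,
    tf_family_enrichment,
    wilcoxon_rank_sum,
)


class TestFisher:
    def test_balanced_table(self):
        res = fisher_2x2(1, 1, 1, 1)
        assert res.odds_ratio == 1.0
        assert res.p == 1.0

    def test_haldane_correction_engages_on_zero_cell(self):
        res = fisher_2x2(10, 0, 5, 5)
        assert np.isfinite(res.odds_ratio)
        assert np.isfinite(res.ci_low) and np.isfinite(res.ci_high)
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_reciprocal_under_row_swap(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, 4)
            r1 = fisher_2x2(a, b, c, d)
            r2 = fisher_2x2(c, d, a, b)
            assert r1.odds_ratio == pytest.approx(1.0 / r2.odds_ratio)
            assert r1.p == pytest.approx(r2.p)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_2x2(0, 0, 3, 4)

    def test_ci_brackets_or(self, rng):
        for _ in range(10):
            a, b, c, d = rng.integers(1, 100, 4)
            res = fisher_2x2(a, b, c, d)
            assert res.ci_low <= res.odds_ratio <= res.ci_high


class TestBinomial:
    def test_exactly_half_gives_p_one(self):
        assert binom_test_two_sided(50, 100, 0.5) == 1.0

    def test_extreme_tail_exact_value(self):
        assert binom_test_two_sided(0, 10, 0.5) == pytest.approx(2 / 1024)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binom_test_two_sided(11, 10, 0.5)


class TestBhAdjust:
    def test_worked_step_up(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == 0.2

    def test_matches_textbook_step_up_oracle(self, rng):
        p = rng.random(100)
        # independent step-up implementation
        order = np.argsort(p)
        n = len(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        np.testing.assert_allclose(bh_adjust(p), adj, atol=1e-12)

    def test_ordering_preserved(self, rng):
        p = np.sort(rng.random(30))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-15).all()
        assert (adj >= p - 1e-15).all()


class TestGlmEnrichment:
    def test_matches_fisher_or_on_2x2(self):
        a, b, c, d = 30, 20, 10, 40  # exposed hits/misses vs unexposed
        outcome = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        labels = np.array(["exposed"] * (a + b) + ["reference"] * (c + d))
        clusters = np.arange(len(outcome))  # each unit its own cluster
        res = glm_enrichment(outcome, labels, clusters, reference="reference")
        expected_or = (a / b) / (c / d)
        assert res[0].odds_ratio == pytest.approx(expected_or, rel=1e-6)

    def test_duplicating_units_within_cluster_keeps_robust_ci(self, rng):
        """Cluster-robust errors should be unchanged when every unit is
        duplicated inside its own cluster."""
        n = 40
        outcome = rng.integers(0, 2, n)
        labels = np.array(["a", "b"] * (n // 2))
        clusters = np.arange(n)
        base = glm_enrichment(outcome, labels, clusters)[0]
        dup = glm_enrichment(
            np.repeat(outcome, 2), np.repeat(labels, 2), np.repeat(clusters, 2)
        )[0]
        assert dup.odds_ratio == pytest.approx(base.odds_ratio, rel=1e-6)
        # the sandwich itself is invariant; statsmodels' small-sample
        # correction shifts the CI by O(1/n)
        assert dup.ci_low == pytest.approx(base.ci_low, rel=0.05)
        assert dup.ci_high == pytest.approx(base.ci_high, rel=0.05)

    def test_type_i_error_calibrated_under_null(self, rng):
        """Outcome independent of class: rejections at alpha = 0.05 stay
        within binomial tolerance over repetitions."""
        rejections = 0
        reps = 120
        for _ in range(reps):
            outcome = rng.integers(0, 2, 300)
            labels = rng.choice(["a", "b"], 300)
            clusters = np.arange(300)
            res = glm_enrichment(outcome, labels, clusters)[0]
            rejections += res.p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_separation_flagged(self):
        outcome = np.array([1] * 20 + [0] * 20)
        labels = np.array(["a"] * 20 + ["b"] * 20)  # perfect separation
        res = glm_enrichment(outcome, labels, np.arange(40))[0]
        assert res.flagged
        assert np.isnan(res.ci_low)


class TestPermutationEnrichment:
    def _inputs(self, rng, n_bg=60, n_class=30, class_rate=0.05, bg_rate=0.05):
        m = rng.integers(5, 30, n_bg + n_class)
        rates = np.array([bg_rate] * n_bg + [class_rate] * n_class)
        h = rng.binomial(m, rates)
        chroms = rng.choice(["chr1", "chr2"], n_bg + n_class)
        labels = np.array(["background"] * n_bg + ["test_class"] * n_class)
        bg = np.array([True] * n_bg + [False] * n_class)
        return h, m, chroms, labels, bg

    def test_matched_rate_gives_moderate_p(self, rng):
        h, m, chroms, labels, bg = self._inputs(rng)
        out = permutation_enrichment(h, m, chroms, labels, bg, n_perm=10_000, rng=rng)
        assert 0.05 < out["test_class"].p_one_sided < 0.95

    def test_saturated_class_hits_reporting_floor(self, rng):
        h, m, chroms, labels, bg = self._inputs(rng, class_rate=0.05)
        h[~bg] = m[~bg]  # every callable variant in the class is a hit
        out = permutation_enrichment(h, m, chroms, labels, bg, n_perm=10_000, rng=rng)
        res = out["test_class"]
        assert res.at_floor
        assert res.p_one_sided == pytest.approx(1 / 10_001)
        assert res.report_p().startswith("<")

    def test_deterministic_under_fixed_seed(self, rng):
        h, m, chroms, labels, bg = self._inputs(rng)
        a = permutation_enrichment(h, m, chroms, labels, bg, n_perm=2_000, seed=5)
        b = permutation_enrichment(h, m, chroms, labels, bg, n_perm=2_000, seed=5)
        assert a["test_class"].p_one_sided == b["test_class"].p_one_sided

    def test_zero_callable_size_rejected(self, rng):
        h, m, chroms, labels, bg = self._inputs(rng)
        m[0] = 0
        with pytest.raises(ValueError, match="callable"):
            permutation_enrichment(h, m, chroms, labels, bg, n_perm=100, rng=rng)


class TestProportionChisq:
    def test_identical_rows_give_p_one(self):
        chi2, p = proportion_chisq(np.array([[10, 20, 30], [10, 20, 30]]))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_2x2_worked_value(self):
        chi2, p = proportion_chisq(np.array([[10, 0], [0, 10]]))
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            proportion_chisq(np.array([[0, 0], [1, 2]]))


def test_wilcoxon_wrapper_matches_scipy(rng):
    x, y = rng.standard_normal(30), rng.standard_normal(30) + 0.5
    stat, p = wilcoxon_rank_sum(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert p == pytest.approx(ref.pvalue)


def test_tf_family_enrichment_excludes_sparse_families(rng):
    rows = []
    for fam, n_hits in (("ETS", 30), ("RARE", 3)):
        for i in range(60):
            rows.append(
                {
                    "variant_id": f"{fam}_{i}",
                    "family": fam,
                    "annotation": "promoter" if i % 2 else "cis-CRE",
                    "hit": i < n_hits,
                }
            )
    out = tf_family_enrichment(pd.DataFrame(rows), min_hits=10)
    assert set(out["family"]) == {"ETS"}
    assert (out["p_adj"] >= out["p"] - 1e-15).all()
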