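import numpy as np
import pandas as pd
import pytest

from molqtl.integrate import (
    GROUPS,
    coverage_compare,
    effect_concordance,
    harmonize_alleles,
    membership_groups,
    stratify_groups,
)
from molqtl.model import CredibleSet, CsMember


def _cs(cs_id, qtl_type, variant_ids):
    return CredibleSet(
        cs_id=cs_id,
        qtl_type=qtl_type,
        feature_id=f"feat_{cs_id}",
        members=[CsMember(v, 0.1, 0.0) for v in variant_ids],
    )


class TestMembershipGroups:
    def test_scored_caqtl_without_coloc(self):
        caqtl = [_cs("c1", "caQTL", ["v1", "v2"])]
        out = membership_groups([], caqtl, [], {"v2"})
        assert out.loc[0, "group"] == "chrombpnet_caQTL"

    def test_colocalized_pair_without_score(self):
        eqtl = [_cs("e1", "eQTL", ["v1"])]
        caqtl = [_cs("c1", "caQTL", ["v2"])]
        out = membership_groups(eqtl, caqtl, [("e1", "c1")], set())
        assert list(out["group"]) == ["caQTL_eQTL"]

    def test_orphan_scored_variant_is_score_only(self):
        out = membership_groups([], [], [], {"v_lonely"})
        assert list(out["group"]) == ["chrombpnet_only"]
        assert out.loc[0, "variant_id"] == "v_lonely"

    def test_scored_variant_inside_cs_not_double_counted(self):
        caqtl = [_cs("c1", "caQTL", ["v1"])]
        out = membership_groups([], caqtl, [], {"v1"})
        assert list(out["group"]) == ["chrombpnet_caQTL"]
        assert len(out) == 1

    def test_groups_partition_against_brute_force_set_algebra(self, rng):
        """Group counts match direct set algebra over a random instance."""
        variants = [f"v{i}" for i in range(200)]
        eqtl = [
            _cs(f"e{i}", "eQTL", list(rng.choice(variants, 3, replace=False)))
            for i in range(20)
        ]
        caqtl = [
            _cs(f"c{i}", "caQTL", list(rng.choice(variants, 3, replace=False)))
            for i in range(25)
        ]
        pairs = [(f"e{i}", f"c{i}") for i in range(8)]
        scored = set(rng.choice(variants, 60, replace=False))
        out = membership_groups(eqtl, caqtl, pairs, scored)

        # exhaustive and exclusive
        assert len(out) == len(set(out["unit_id"]))
        assert set(out["group"]) <= set(GROUPS)
        n_pairs = len(pairs)
        n_solo_c = len(caqtl) - n_pairs
        n_solo_e = len(eqtl) - n_pairs
        cs_vars = {v for cs in eqtl + caqtl for v in cs.variant_ids}
        n_orphans = len(scored - cs_vars)
        assert len(out) == n_pairs + n_solo_c + n_solo_e + n_orphans

        for _, row in out.iterrows():
            if row["group"] in ("caQTL_eQTL", "chrombpnet_caQTL_eQTL"):
                e = next(cs for cs in eqtl if cs.cs_id == row["eqtl_cs"])
                c = next(cs for cs in caqtl if cs.cs_id == row["caqtl_cs"])
                has = bool((set(e.variant_ids) | set(c.variant_ids)) & scored)
                assert (row["group"] == "chrombpnet_caQTL_eQTL") == has


class TestStratify:
    def test_uniform_low_maf_group(self):
        groups = pd.DataFrame(
            {"unit_id": ["u1"], "group": ["caQTL_only"], "eqtl_cs": [None],
             "caqtl_cs": ["c1"], "variant_id": [None]}
        )
        vt = pd.DataFrame({"id": [f"v{i}" for i in range(10)], "maf": 0.07})
        out = stratify_groups(
            groups,
            {"u1": [f"v{i}" for i in range(10)]},
            vt,
            {},
            {},
        )
        maf_rows = out[(out["axis"] == "maf")]
        low = maf_rows[maf_rows["bin"] == "[0.05,0.1)"]
        assert low["proportion"].iloc[0] == 1.0

    def test_proportions_sum_to_one_per_axis(self, rng):
        variants = [f"v{i}" for i in range(50)]
        vt = pd.DataFrame({"id": variants, "maf": rng.uniform(0.05, 0.5, 50)})
        annos = {v: rng.choice(["promoter", "cis-CRE", "non-peak"]) for v in variants}
        cats = {v: rng.choice(["C1", "C2", "C3"]) for v in variants}
        groups = pd.DataFrame(
            {"unit_id": ["u1", "u2"], "group": ["caQTL_only"] * 2,
             "eqtl_cs": [None] * 2, "caqtl_cs": ["c1", "c2"], "variant_id": [None] * 2}
        )
        out = stratify_groups(
            groups, {"u1": variants[:30], "u2": variants[30:]}, vt, annos, cats
        )
        for axis, grp in out.groupby("axis"):
            assert grp["proportion"].sum() == pytest.approx(1.0)


class TestEffectConcordance:
    def _inputs(self, log_afc, beta, cats=None):
        n = len(log_afc)
        vids = [f"v{i}" for i in range(n)]
        scores = pd.DataFrame({"variant_id": vids, "log_afc": log_afc})
        assocs = pd.DataFrame({"variant_id": vids, "beta": beta})
        categories = cats or {v: "C1" for v in vids}
        return scores, assocs, categories, set(vids), set(vids)

    def test_identical_vectors_give_r_one(self, rng):
        x = rng.normal(0, 1, 30)
        scores, assocs, cats, s, c = self._inputs(x, x)
        out = effect_concordance(scores, assocs, cats, s, c)
        assert out["both_significant"]["r"] == pytest.approx(1.0)

    def test_out_of_peak_variants_excluded(self, rng):
        x = rng.normal(0, 1, 20)
        cats = {f"v{i}": ("C3" if i < 10 else "C1") for i in range(20)}
        scores, assocs, _, s, c = self._inputs(x, x)
        out = effect_concordance(scores, assocs, cats, s, c)
        assert out["both_significant"]["n"] == 10

    def test_joint_significance_class_shows_highest_r2(self, rng):
        """With concordance planted only among jointly significant variants,
        the both-significant class outranks the single-method classes."""
        n = 300
        true = rng.normal(0, 1, n)
        beta = true + 0.3 * rng.normal(0, 1, n)
        log_afc = 0.7 * true + np.sqrt(1 - 0.49) * rng.normal(0, 1, n)
        vids = [f"v{i}" for i in range(n)]
        scores = pd.DataFrame({"variant_id": vids, "log_afc": log_afc})
        assocs = pd.DataFrame({"variant_id": vids, "beta": beta})
        cats = {v: "C1" for v in vids}
        strong = np.abs(true) > 1.0
        score_sig = {v for v, s_ in zip(vids, strong) if s_}
        caqtl_sig = set(score_sig)
        weak = [v for v in vids if v not in score_sig]
        caqtl_sig |= set(weak[: len(weak) // 2])
        out = effect_concordance(scores, assocs, cats, score_sig, caqtl_sig)
        assert out["both_significant"]["r2"] > out["caqtl_only"]["r2"]

    def test_simultaneous_allele_flip_invariance(self, rng):
        x = rng.normal(0, 1, 40)
        y = 0.8 * x + 0.2 * rng.normal(0, 1, 40)
        scores, assocs, cats, s, c = self._inputs(x, y)
        base = effect_concordance(scores, assocs, cats, s, c)
        scores_f, assocs_f, *_ = self._inputs(-x, -y)
        flipped = effect_concordance(scores_f, assocs_f, cats, s, c)
        assert base["both_significant"]["r"] == pytest.approx(
            flipped["both_significant"]["r"]
        )


class TestHarmonize:
    def test_swapped_alleles_flip_beta(self):
        scores = pd.DataFrame(
            {"variant_id": ["v1"], "log_afc": [0.5], "ref": ["A"], "alt": ["G"]}
        )
        assocs = pd.DataFrame(
            {"variant_id": ["v1"], "beta": [0.3], "ref": ["G"], "alt": ["A"]}
        )
        out = harmonize_alleles(scores, assocs)
        assert out["beta"].iloc[0] == pytest.approx(-0.3)

    def test_irreconcilable_alleles_excluded(self):
        scores = pd.DataFrame(
            {"variant_id": ["v1"], "log_afc": [0.5], "ref": ["A"], "alt": ["G"]}
        )
        assocs = pd.DataFrame(
            {"variant_id": ["v1"], "beta": [0.3], "ref": ["C"], "alt": ["T"]}
        )
        assert len(harmonize_alleles(scores, assocs)) == 0


class TestCoverageCompare:
    def test_identical_groups_near_null(self, rng):
        x = rng.normal(100, 10, 500)
        res = coverage_compare(x, x.copy())
        assert abs(res.t_statistic) < 1e-10
        assert res.p_value > 0.99

    def test_planted_shift_detected(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        res = coverage_compare(a, b)
        assert res.p_value < 1e-10

    def test_matches_textbook_formula_on_toy_instance(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        res = coverage_compare(a, b)
        sa2, sb2 = a.var(ddof=1), b.var(ddof=1)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sa2 / 3 + sb2 / 3)
        assert res.t_statistic == pytest.approx(t_hand)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            coverage_compare(np.array([1.0]), np.array([1.0, 2.0]))
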