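import numpy as np
import pandas as pd
import pytest

from molqtl.annotate import STATE_PRIORITY
from molqtl.qtl import residualize
from molqtl.synthetic import (
    SimConfig,
    emit_features,
    emit_gwas_credsets,
    emit_variant_scores,
    make_truth,
    scores_from_effects,
    simulate_cohort,
    simulate_genotypes,
    simulate_phenotypes,
)


def small_config(**kw):
    defaults = dict(
        n_individuals=100,
        n_chromosomes=1,
        n_ld_blocks=10,
        variants_per_block=10,
        n_genes=12,
        n_peaks=12,
        n_causal_loci=8,
        n_gwas_credsets=4,
        seed=3,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(frac_chrom_to_gene=0.5, frac_gene_to_chrom=0.5, frac_independent=0.5)

    def test_small_cohort_refused(self):
        with pytest.raises(ValueError, match="30"):
            small_config(n_individuals=10)

    def test_maf_range_bounds(self):
        with pytest.raises(ValueError, match="maf_range"):
            small_config(maf_range=(0.01, 0.5))


class TestGenotypes:
    def test_deterministic_under_fixed_seed(self):
        d1, v1 = simulate_genotypes(small_config())
        d2, v2 = simulate_genotypes(small_config())
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(v1, v2)

    def test_empirical_maf_at_least_five_percent(self):
        dosages, variants = simulate_genotypes(small_config(n_individuals=200))
        freqs = dosages.mean(axis=0) / 2.0
        maf = np.minimum(freqs, 1 - freqs)
        assert (maf >= 0.05).all()
        assert (variants["maf"] >= 0.05).all()

    def test_zero_copy_probability_gives_independent_variants(self):
        config = small_config(n_individuals=500, ld_copy_prob=0.0, n_ld_blocks=1, variants_per_block=10)
        dosages, _ = simulate_genotypes(config)
        corr = np.corrcoef(dosages.to_numpy().T)
        off_diag = corr[~np.eye(10, dtype=bool)]
        assert np.abs(off_diag).max() < 0.15

    def test_copy_probability_one_duplicates_columns(self):
        config = small_config(ld_copy_prob=1.0, n_ld_blocks=1, variants_per_block=5)
        dosages, _ = simulate_genotypes(config)
        mat = dosages.to_numpy()
        for j in range(1, 5):
            np.testing.assert_array_equal(mat[:, j], mat[:, 0])

    def test_adjacent_correlation_decays_within_block(self):
        config = small_config(n_individuals=500, ld_copy_prob=0.9, n_ld_blocks=2, variants_per_block=15)
        dosages, _ = simulate_genotypes(config)
        mat = dosages.to_numpy()
        block = mat[:, :15]
        r_adjacent = np.mean(
            [abs(np.corrcoef(block[:, j], block[:, j + 1])[0, 1]) for j in range(14)]
        )
        r_far = abs(np.corrcoef(block[:, 0], block[:, 14])[0, 1])
        assert r_adjacent > 0.6
        assert r_far < r_adjacent


class TestTruth:
    def test_architecture_partition_exact_when_integral(self):
        rng = np.random.default_rng(0)
        config = small_config(
            n_causal_loci=10,
            frac_chrom_to_gene=0.4,
            frac_gene_to_chrom=0.4,
            frac_independent=0.2,
        )
        _, vt = simulate_genotypes(config)
        truth = make_truth(config, vt, rng)
        counts = truth.loci["architecture"].value_counts()
        assert counts["chrom_to_gene"] == 4
        assert counts["gene_to_chrom"] == 4
        assert counts["independent"] == 2

    def test_causal_variants_exist_in_genotypes(self):
        cohort = simulate_cohort(small_config())
        assert set(cohort.truth.loci["variant_id"]) <= set(cohort.dosages.columns)

    def test_directional_loci_have_nonzero_path_coefficients(self):
        cohort = simulate_cohort(small_config())
        directional = cohort.truth.loci[
            cohort.truth.loci["architecture"] != "independent"
        ]
        assert (directional["beta"].abs() >= 0.5).all()
        assert (directional["path_coeff"].abs() > 0).all()


class TestPhenotypes:
    def test_zero_effect_gives_no_genotype_association(self):
        rng = np.random.default_rng(5)
        config = small_config(n_individuals=400, effect_size_sd=1e-9, min_effect=0.0)
        dosages, vt = simulate_genotypes(config, rng)
        truth = make_truth(config, vt, rng)
        expr, acc, cov = simulate_phenotypes(dosages, config, truth, rng)
        for row in truth.loci.itertuples(index=False):
            g = dosages[row.variant_id].to_numpy()
            r = np.corrcoef(g, expr[row.gene].to_numpy())[0, 1]
            assert abs(r) < 0.2

    def test_noiseless_chain_is_d_separated(self):
        """With zero noise, partialling the peak out of the gene removes all
        genotype association at chromatin-to-gene loci."""
        rng = np.random.default_rng(8)
        config = small_config(
            n_individuals=300,
            noise_sd=1e-9,
            frac_chrom_to_gene=1.0,
            frac_gene_to_chrom=0.0,
            frac_independent=0.0,
            age_effect=0.0,
            sex_effect=0.0,
        )
        dosages, vt = simulate_genotypes(config, rng)
        truth = make_truth(config, vt, rng)
        expr, acc, cov = simulate_phenotypes(dosages, config, truth, rng)
        row = truth.loci.iloc[0]
        g = dosages[row["variant_id"]].to_numpy()
        gene = expr[row["gene"]].to_numpy()
        peak = acc[row["peak"]].to_numpy()
        gene_resid = residualize(gene[:, None], peak[:, None])[:, 0]
        partial_r = np.corrcoef(g, gene_resid)[0, 1]
        assert abs(partial_r) < 1e-3

    def test_ols_recovers_planted_effect_within_two_se(self):
        rng = np.random.default_rng(21)
        config = small_config(n_individuals=400, effect_size_sd=0.0, min_effect=0.8)
        dosages, vt = simulate_genotypes(config, rng)
        truth = make_truth(config, vt, rng)
        expr, acc, cov = simulate_phenotypes(dosages, config, truth, rng)
        C = cov.to_numpy()
        for row in truth.loci.itertuples(index=False):
            if row.architecture == "gene_to_chrom":
                pheno = expr[row.gene].to_numpy()
            else:
                pheno = acc[row.peak].to_numpy()
            y = residualize(pheno[:, None], C)[:, 0]
            g = residualize(dosages[row.variant_id].to_numpy()[:, None], C)[:, 0]
            slope = (g @ y) / (g @ g)
            resid = y - slope * g
            se = np.sqrt((resid @ resid) / (len(g) - 4) / (g @ g))
            assert abs(slope - row.beta) < 2.5 * se


class TestFeatures:
    def test_state_labels_from_closed_vocabulary(self, small_cohort):
        assert set(small_cohort.segmentation["label"]) <= set(STATE_PRIORITY)

    def test_segmentation_tiles_each_chromosome(self, small_cohort):
        config = small_cohort.config
        for chrom, grp in small_cohort.segmentation.groupby("chrom"):
            grp = grp.sort_values("start")
            assert grp["start"].iloc[0] == 0
            assert grp["end"].iloc[-1] == config.chrom_length
            assert (grp["end"].to_numpy()[:-1] == grp["start"].to_numpy()[1:]).all()
            assert (grp["end"] - grp["start"]).sum() == config.chrom_length

    def test_single_peak_round_trips_through_bed(self, tmp_path):
        from molqtl.io import read_bed, write_bed

        cohort = simulate_cohort(small_config(n_peaks=8))
        peak = cohort.peak_table.iloc[[0]].rename(columns={"id": "name"})
        write_bed(peak[["chrom", "start", "end", "name"]], tmp_path / "p.bed")
        back = read_bed(tmp_path / "p.bed")
        assert back.loc[0, "start"] == peak["start"].iloc[0]
        assert back.loc[0, "end"] == peak["end"].iloc[0]
        assert back.loc[0, "name"] == peak["name"].iloc[0]

    def test_peak_summit_inside_interval(self, small_cohort):
        pt = small_cohort.peak_table
        assert ((pt["summit"] >= pt["start"]) & (pt["summit"] < pt["end"])).all()


class TestVariantScores:
    def test_only_in_peak_variants_scored(self, small_cohort):
        vt = small_cohort.variant_table.set_index("id")
        for vid in small_cohort.variant_scores["variant_id"]:
            pos, chrom = vt.loc[vid, "pos"], vt.loc[vid, "chrom"]
            peaks = small_cohort.peak_table
            inside = (
                (peaks["chrom"] == chrom)
                & (peaks["start"] <= pos)
                & (pos < peaks["end"])
            ).any()
            assert inside

    def test_significance_flag_consistent_with_p(self, small_cohort):
        vs = small_cohort.variant_scores
        assert (vs["significant"] == (vs["p_empirical"] < 0.05)).all()

    def test_perfect_concordance_perfect_rank_correlation(self, rng):
        effects = rng.normal(0, 1, 500)
        scores = scores_from_effects(effects, concordance=1.0, rng=rng)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(effects, scores)
        assert rho == pytest.approx(1.0)

    def test_planted_concordance_recovered(self, rng):
        """At concordance 0.65 with 2,000 scored variants the Pearson r
        lands inside the sampling band [0.55, 0.75]."""
        effects = rng.normal(0, 1, 2000)
        scores = scores_from_effects(effects, concordance=0.65, rng=rng)
        r = np.corrcoef(effects, scores)[0, 1]
        assert 0.55 < r < 0.75


class TestGwasCredsets:
    def test_deterministic_under_fixed_seed(self):
        c1 = simulate_cohort(small_config())
        c2 = simulate_cohort(small_config())
        pd.testing.assert_frame_equal(c1.gwas_credsets, c2.gwas_credsets)

    def test_sharing_fraction_zero_plants_no_causal_overlap(self):
        cohort = simulate_cohort(small_config(gwas_sharing_frac=0.0))
        assert not cohort.gwas_credsets["shared_with_molqtl"].any()

    def test_sharing_fraction_one_always_overlaps(self):
        cohort = simulate_cohort(small_config(gwas_sharing_frac=1.0))
        assert cohort.gwas_credsets["shared_with_molqtl"].all()

    def test_causal_variant_gets_top_bayes_factor(self):
        cohort = simulate_cohort(small_config(gwas_sharing_frac=1.0))
        for cs_id, grp in cohort.gwas_credsets.groupby("cs_id"):
            top = grp.loc[grp["lbf"].idxmax(), "variant_id"]
            causal = grp["causal_variant"].iloc[0]
            # the top-lbf variant is the causal one or a tight LD proxy
            if top != causal:
                g1 = cohort.dosages[top].to_numpy()
                g2 = cohort.dosages[causal].to_numpy()
                assert abs(np.corrcoef(g1, g2)[0, 1]) > 0.6


def test_full_cohort_regeneration_is_identical():
    c1 = simulate_cohort(small_config())
    c2 = simulate_cohort(small_config())
    pd.testing.assert_frame_equal(c1.dosages, c2.dosages)
    pd.testing.assert_frame_equal(c1.expression, c2.expression)
    pd.testing.assert_frame_equal(c1.accessibility, c2.accessibility)
    pd.testing.assert_frame_equal(c1.variant_scores, c2.variant_scores)
    pd.testing.assert_frame_equal(c1.truth.loci, c2.truth.loci)
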