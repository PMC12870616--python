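"""Ground-truthed synthetic CD4+ T-cell-like cohort.

The generator emulates the statistical structure every downstream stage
assumes: diploid dosages with LD-block structure (haplotype copying within
blocks, independence across blocks), per-individual expression and
accessibility matrices with planted cis effects wired as chromatin-to-gene,
gene-to-chromatin or independent architectures, BED-like feature tables, a
six-supergroup chromatin-state segmentation, sequence-model allelic scores
with tunable concordance to the true in-peak effects, and GWAS credible
sets a stated fraction of which share their causal variant with a molQTL
locus.

Covariates mimic the cohort: age drawn from two bands (young/old) and sex
Bernoulli(0.5), both entering the phenotypes linearly.  Noise is Gaussian
throughout — downstream stages consume normalized matrices, so count-like
transforms are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import STATE_PRIORITY
from .io import write_bed, write_vcf_lite
from .qtl import wakefield_lbf

ARCHITECTURES = ("chrom_to_gene", "gene_to_chrom", "independent")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Effect sizes are in phenotype SD units per ALT allele; planted effects
    are drawn N(0, effect_size_sd) with their magnitude floored at
    ``min_effect`` so every causal locus is detectable at the default sample
    size.  ``chrombpnet_concordance`` is the target correlation between true
    in-peak accessibility effects and emitted sequence-model scores.
    """

    n_individuals: int = 400
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_ld_blocks: int = 40  # per chromosome
    variants_per_block: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 100
    n_peaks: int = 180
    n_causal_loci: int = 80
    effect_size_sd: float = 0.8
    min_effect: float = 0.5
    path_coeff_range: tuple[float, float] = (0.6, 1.2)
    noise_sd: float = 1.0
    frac_chrom_to_gene: float = 0.4
    frac_gene_to_chrom: float = 0.4
    frac_independent: float = 0.2
    ld_copy_prob: float = 0.9
    frac_causal_in_peak: float = 0.6
    chrombpnet_concordance: float = 0.7
    frac_score_specific: float = 0.1
    n_gwas_credsets: int = 24
    n_gwas_traits: int = 4
    gwas_sharing_frac: float = 0.5
    age_effect: float = 0.3
    sex_effect: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_chrom_to_gene + self.frac_gene_to_chrom + self.frac_independent
        if abs(total - 1.0) > 1e-9:
            raise ValueError("architecture fractions must sum to 1")
        lo, hi = self.maf_range
        if not (0.05 <= lo < hi <= 0.5):
            raise ValueError("maf_range must sit inside [0.05, 0.5]")
        if self.n_individuals < 30:
            raise ValueError("n_individuals < 30: downstream regression unstable")
        if self.n_causal_loci > min(self.n_genes, self.n_peaks):
            raise ValueError("n_causal_loci exceeds the number of genes or peaks")


@dataclass
class CohortTruth:
    """Ground truth for parameter-recovery tests.

    One record per causal locus: the causal variant, the paired gene and
    peak, the architecture, the allelic effect on the mediator and the
    mediator-to-outcome path coefficient.  ``true_effects`` maps each causal
    variant to its total (peak effect, gene effect) in phenotype SD units.
    """

    loci: pd.DataFrame = field(default_factory=pd.DataFrame)
    true_effects: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "loci": self.loci.to_dict(orient="records"),
                    "true_effects": self.true_effects,
                },
                indent=1,
            )
        )


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Diploid dosages with LD blocks; returns (dosage matrix, variant table).

    Within a block all variants share an allele frequency and each haplotype
    copies its neighbor's allele with probability ``ld_copy_prob`` (fresh
    draw otherwise), so pairwise r decays geometrically with variant
    distance; blocks are independent.  Columns whose empirical MAF falls
    below 0.05 are resampled.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_individuals
    lo, hi = config.maf_range
    bases = np.array(list("ACGT"))

    dosage_cols = []
    var_rows = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        block_span = config.chrom_length // config.n_ld_blocks
        for b in range(config.n_ld_blocks):
            p = rng.uniform(lo, hi)
            haps = np.empty((2 * n, config.variants_per_block), dtype=np.int8)
            haps[:, 0] = rng.random(2 * n) < p
            for j in range(1, config.variants_per_block):
                copy = rng.random(2 * n) < config.ld_copy_prob
                fresh = rng.random(2 * n) < p
                haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
            # enforce empirical MAF >= 0.05 per column
            for j in range(config.variants_per_block):
                for _ in range(100):
                    freq = haps[:, j].mean()
                    if 0.05 <= freq <= 0.95:
                        break
                    haps[:, j] = rng.random(2 * n) < rng.uniform(max(lo, 0.1), hi)
            dos = haps[:n] + haps[n:]
            spacing = block_span // (config.variants_per_block + 1)
            for j in range(config.variants_per_block):
                pos = b * block_span + (j + 1) * spacing
                vid = f"{chrom}_v{b * config.variants_per_block + j}"
                freq = dos[:, j].mean() / 2.0
                maf = min(freq, 1.0 - freq)
                ref, alt = rng.choice(bases, size=2, replace=False)
                var_rows.append((vid, chrom, int(pos), str(ref), str(alt), float(maf)))
            dosage_cols.append(dos)

    variant_table = pd.DataFrame(
        var_rows, columns=["id", "chrom", "pos", "ref", "alt", "maf"]
    )
    dosages = pd.DataFrame(
        np.hstack(dosage_cols).astype(float),
        index=[f"ind_{i}" for i in range(n)],
        columns=variant_table["id"].tolist(),
    )
    return dosages, variant_table


def _architecture_labels(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Exact per-fraction partition of loci over architectures (rounded
    largest-remainder when fractions x n_loci are not integral)."""
    n = config.n_causal_loci
    fracs = np.array(
        [config.frac_chrom_to_gene, config.frac_gene_to_chrom, config.frac_independent]
    )
    counts = np.floor(fracs * n).astype(int)
    remainder = fracs * n - counts
    for k in np.argsort(-remainder)[: n - counts.sum()]:
        counts[k] += 1
    labels = np.repeat(ARCHITECTURES, counts)
    rng.shuffle(labels)
    return labels


def make_truth(
    config: SimConfig,
    variant_table: pd.DataFrame,
    rng: np.random.Generator,
) -> CohortTruth:
    """Pick one causal variant per locus (one LD block each, so loci are
    independent), pair it with a gene and a peak, assign architectures and
    draw effects."""
    n_blocks_total = config.n_chromosomes * config.n_ld_blocks
    if config.n_causal_loci > n_blocks_total:
        raise ValueError("need at least one LD block per causal locus")
    block_ids = rng.choice(n_blocks_total, size=config.n_causal_loci, replace=False)
    labels = _architecture_labels(config, rng)

    rows = []
    effects: dict[str, tuple[float, float]] = {}
    for k, (blk, arch) in enumerate(zip(block_ids, labels)):
        offset = int(blk) * config.variants_per_block + int(
            rng.integers(config.variants_per_block)
        )
        variant = variant_table.iloc[offset]
        beta = float(
            np.sign(rng.standard_normal())
            * max(abs(rng.normal(0.0, config.effect_size_sd)), config.min_effect)
        )
        gamma = float(
            np.sign(rng.standard_normal()) * rng.uniform(*config.path_coeff_range)
        )
        if arch == "chrom_to_gene":
            peak_eff, gene_eff = beta, beta * gamma
        elif arch == "gene_to_chrom":
            peak_eff, gene_eff = beta * gamma, beta
        else:
            beta2 = float(
                np.sign(rng.standard_normal())
                * max(abs(rng.normal(0.0, config.effect_size_sd)), config.min_effect)
            )
            peak_eff, gene_eff = beta, beta2
        rows.append(
            {
                "locus_id": f"truth_locus_{k}",
                "variant_id": str(variant["id"]),
                "chrom": str(variant["chrom"]),
                "pos": int(variant["pos"]),
                "gene": f"gene_{k}",
                "peak": f"peak_{k}",
                "architecture": str(arch),
                "beta": beta,
                "path_coeff": gamma,
            }
        )
        effects[str(variant["id"])] = (float(peak_eff), float(gene_eff))
    truth = CohortTruth(loci=pd.DataFrame(rows), true_effects=effects)
    # every causal variant must exist in the genotype table
    assert set(truth.loci["variant_id"]) <= set(variant_table["id"])
    return truth


def simulate_covariates(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Age from two uniform bands (young 20-41, old 66-100) and sex ~
    Bernoulli(0.5); age is returned z-standardized for direct use as a
    regression covariate."""
    n = config.n_individuals
    old = rng.random(n) < 0.5
    age = np.where(old, rng.uniform(66, 100, n), rng.uniform(20, 41, n))
    age = (age - age.mean()) / age.std()
    sex = (rng.random(n) < 0.5).astype(float)
    return pd.DataFrame(
        {"age": age, "sex": sex}, index=[f"ind_{i}" for i in range(n)]
    )


def simulate_phenotypes(
    dosages: pd.DataFrame,
    config: SimConfig,
    truth: CohortTruth,
    rng: np.random.Generator,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression and accessibility matrices from linear structural models.

    chrom_to_gene: peak = beta*dosage + covars + noise; gene = gamma*peak +
    covars + noise.  gene_to_chrom is the mirror; independent plants two
    separate allelic paths.  Non-causal features are covariates plus noise.
    """
    n = config.n_individuals
    covariates = (
        covariates if covariates is not None else simulate_covariates(config, rng)
    )
    cov_term = (
        config.age_effect * covariates["age"].to_numpy()
        + config.sex_effect * covariates["sex"].to_numpy()
    )

    expr = {}
    acc = {}
    for row in truth.loci.itertuples(index=False):
        g = dosages[row.variant_id].to_numpy()
        if np.ptp(g) == 0:
            raise ValueError(f"zero-variance dosage for {row.variant_id}")
        noise = lambda: rng.normal(0.0, config.noise_sd, n)  # noqa: E731
        if row.architecture == "chrom_to_gene":
            peak = row.beta * g + cov_term + noise()
            gene = row.path_coeff * peak + cov_term + noise()
        elif row.architecture == "gene_to_chrom":
            gene = row.beta * g + cov_term + noise()
            peak = row.path_coeff * gene + cov_term + noise()
        else:
            peak_eff, gene_eff = truth.true_effects[row.variant_id]
            peak = peak_eff * g + cov_term + noise()
            gene = gene_eff * g + cov_term + noise()
        expr[row.gene] = gene
        acc[row.peak] = peak

    for k in range(config.n_causal_loci, config.n_genes):
        expr[f"gene_{k}"] = cov_term + rng.normal(0.0, config.noise_sd, n)
    for k in range(config.n_causal_loci, config.n_peaks):
        acc[f"peak_{k}"] = cov_term + rng.normal(0.0, config.noise_sd, n)

    idx = dosages.index
    return (
        pd.DataFrame(expr, index=idx),
        pd.DataFrame(acc, index=idx),
        covariates,
    )


def emit_features(
    config: SimConfig,
    truth: CohortTruth,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene, peak, chromatin-state and gene-model tables.

    Causal genes get a TSS within the cis window of their causal variant;
    causal peaks cover their variant for ``frac_causal_in_peak`` of loci and
    sit nearby (but off-variant) otherwise.  The segmentation tiles each
    chromosome with the six supergroups; the simplified gene model places a
    promoter at +/-2 kb of each TSS with alternating exon/intron structure
    downstream.
    """
    peak_width = 600
    genes = []
    peaks = []
    truth_by_gene = {row.gene: row for row in truth.loci.itertuples(index=False)}
    truth_by_peak = {row.peak: row for row in truth.loci.itertuples(index=False)}

    for k in range(config.n_genes):
        gid = f"gene_{k}"
        if gid in truth_by_gene:
            row = truth_by_gene[gid]
            chrom = row.chrom
            tss = int(row.pos + rng.integers(-50_000, 50_000))
        else:
            chrom = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
            tss = int(rng.integers(100_000, config.chrom_length - 100_000))
        tss = int(np.clip(tss, 10_000, config.chrom_length - 60_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((gid, chrom, tss, strand, tss, tss + 50_000))

    for k in range(config.n_peaks):
        pid = f"peak_{k}"
        if pid in truth_by_peak:
            row = truth_by_peak[pid]
            chrom = row.chrom
            if rng.random() < config.frac_causal_in_peak:
                start = int(row.pos - rng.integers(50, peak_width - 50))
            else:
                start = int(row.pos + rng.integers(1_000, 20_000))
        else:
            chrom = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
            start = int(rng.integers(1_000, config.chrom_length - peak_width - 1_000))
        start = int(np.clip(start, 0, config.chrom_length - peak_width))
        end = start + peak_width
        summit = int(start + peak_width // 2)
        peaks.append((pid, chrom, start, end, summit))

    gene_table = pd.DataFrame(
        genes, columns=["id", "chrom", "tss", "strand", "start", "end"]
    )
    peak_table = pd.DataFrame(peaks, columns=["id", "chrom", "start", "end", "summit"])
    # per-peak mean read coverage (arbitrary depth units) for the
    # coverage-comparison analysis downstream
    peak_table["coverage"] = np.maximum(rng.normal(100.0, 20.0, len(peak_table)), 5.0)

    # chromatin-state tiling: fixed-width segments with labels drawn from the
    # six supergroups
    seg_rows = []
    seg_width = 50_000
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for s in range(0, config.chrom_length, seg_width):
            label = STATE_PRIORITY[int(rng.integers(len(STATE_PRIORITY)))]
            seg_rows.append((chrom, s, min(s + seg_width, config.chrom_length), label))
    segmentation = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "label"])

    # simplified gene model: promoter +/-2 kb of TSS, then alternating
    # exon(coding)/intron blocks over the gene body; UTRs flank the body
    gm_rows = []
    for row in gene_table.itertuples(index=False):
        gm_rows.append((row.chrom, row.tss - 2_000, row.tss + 2_000, "promoter"))
        body_start = row.tss + 2_000
        gm_rows.append((row.chrom, body_start, body_start + 500, "fiveUTR"))
        cursor = body_start + 500
        for _ in range(3):
            gm_rows.append((row.chrom, cursor, cursor + 1_500, "coding"))
            gm_rows.append((row.chrom, cursor + 1_500, cursor + 1_520, "spliceSite"))
            gm_rows.append((row.chrom, cursor + 1_520, cursor + 12_000, "intron"))
            cursor += 12_000
        gm_rows.append((row.chrom, cursor, cursor + 800, "threeUTR"))
    gene_model = pd.DataFrame(gm_rows, columns=["chrom", "start", "end", "label"])
    gene_model = gene_model[gene_model["start"] >= 0].reset_index(drop=True)

    return gene_table, peak_table, segmentation, gene_model


def scores_from_effects(
    true_effects: np.ndarray,
    concordance: float,
    rng: np.random.Generator,
    scale: float = 0.5,
) -> np.ndarray:
    """Emit sequence-model scores correlated with the true effects at the
    requested level: score = c*standardize(effect) + sqrt(1-c^2)*noise,
    rescaled to a log-aFC-like magnitude."""
    t = np.asarray(true_effects, dtype=float)
    sd = t.std()
    z = (t - t.mean()) / sd if sd > 0 else np.zeros_like(t)
    noise = rng.standard_normal(len(t))
    return scale * (concordance * z + np.sqrt(max(0.0, 1.0 - concordance**2)) * noise)


def emit_variant_scores(
    truth: CohortTruth,
    variant_table: pd.DataFrame,
    peak_table: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sequence-model allelic scores for in-peak variants only.

    The emitted log fold-change correlates with the true in-peak
    accessibility effect at ``chrombpnet_concordance``; a configurable
    fraction of low-MAF null variants additionally receive boosted,
    significant scores with no planted QTL effect (score-specific variants).
    Empirical p-values come from the null score scale, and ``significant``
    is exactly p < 0.05.
    """
    vt = variant_table.reset_index(drop=True)
    in_peak = np.zeros(len(vt), dtype=bool)
    for chrom, grp in peak_table.groupby("chrom"):
        sel = vt["chrom"] == chrom
        pos = vt.loc[sel, "pos"].to_numpy()
        hit = np.zeros(len(pos), dtype=bool)
        for prow in grp.itertuples(index=False):
            hit |= (pos >= prow.start) & (pos < prow.end)
        in_peak[np.flatnonzero(sel)[hit]] = True

    scored = vt[in_peak].reset_index(drop=True)
    true_eff = np.array(
        [truth.true_effects.get(v, (0.0, 0.0))[0] for v in scored["id"]]
    )
    scores = scores_from_effects(true_eff, config.chrombpnet_concordance, rng)

    # score-specific boost for a fraction of low-MAF variants with no
    # planted effect
    null_mask = true_eff == 0.0
    low_maf = scored["maf"].to_numpy() < 0.1
    candidates = np.flatnonzero(null_mask & low_maf)
    n_boost = int(round(config.frac_score_specific * len(candidates)))
    if n_boost > 0:
        picked = rng.choice(candidates, size=n_boost, replace=False)
        null_scale = 0.5 * np.sqrt(max(1e-12, 1.0 - config.chrombpnet_concordance**2))
        scores[picked] += np.sign(rng.standard_normal(n_boost)) * rng.uniform(
            3.0, 5.0, n_boost
        ) * null_scale

    null_sd = 0.5 * np.sqrt(max(1e-12, 1.0 - config.chrombpnet_concordance**2))
    from scipy import stats as _stats

    p_emp = 2.0 * _stats.norm.sf(np.abs(scores) / null_sd)
    return pd.DataFrame(
        {
            "variant_id": scored["id"].to_numpy(),
            "log_afc": scores,
            "p_empirical": p_emp,
            "significant": p_emp < 0.05,
        }
    )


def emit_gwas_credsets(
    truth: CohortTruth,
    variant_table: pd.DataFrame,
    dosages: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    gwas_n: int = 50_000,
    prior_variance: float = 0.04,
) -> pd.DataFrame:
    """GWAS credible sets with per-variant log Bayes factors.

    ``gwas_sharing_frac`` of the credible sets are planted on a molQTL
    causal variant (these should colocalize downstream); the rest sit on
    non-causal variants.  Per-variant z-scores follow the LD profile of the
    causal variant (z_j = r_j * z_causal + noise) and become Wakefield log
    Bayes factors at GWAS-scale sampling variance.
    """
    vt = variant_table.reset_index(drop=True)
    n_shared = int(round(config.gwas_sharing_frac * config.n_gwas_credsets))
    causal_pool = truth.loci["variant_id"].tolist()
    shared_causals = list(
        rng.choice(causal_pool, size=min(n_shared, len(causal_pool)), replace=False)
    )
    non_causal_pool = vt[~vt["id"].isin(causal_pool)]["id"].tolist()
    other_causals = list(
        rng.choice(
            non_causal_pool,
            size=config.n_gwas_credsets - len(shared_causals),
            replace=False,
        )
    )

    rows = []
    for k, causal in enumerate(shared_causals + other_causals):
        trait = f"trait_{k % config.n_gwas_traits}"
        c_idx = int(vt.index[vt["id"] == causal][0])
        chrom = vt.loc[c_idx, "chrom"]
        # region: the surrounding variants on the same chromosome
        lo = max(0, c_idx - 15)
        hi = min(len(vt), c_idx + 16)
        region = vt.iloc[lo:hi]
        region = region[region["chrom"] == chrom]
        g_c = dosages[causal].to_numpy()
        g_c = (g_c - g_c.mean()) / g_c.std()
        z_c = float(np.sign(rng.standard_normal()) * rng.uniform(7.0, 10.0))
        z = []
        for vid in region["id"]:
            g = dosages[vid].to_numpy()
            sd = g.std()
            r = float(np.corrcoef(g_c, (g - g.mean()) / sd)[0, 1]) if sd > 0 else 0.0
            z.append(r * z_c + rng.standard_normal())
        z = np.asarray(z)
        maf = region["maf"].to_numpy()
        v = 1.0 / (2.0 * maf * (1.0 - maf) * gwas_n)
        lbf = wakefield_lbf(z, v, prior_variance)
        pip = np.exp(lbf - lbf.max())
        pip = pip / pip.sum()
        keep = np.argsort(-pip)[: max(1, int((pip > 0.01).sum()))]
        for j in keep:
            rows.append(
                {
                    "trait": trait,
                    "cs_id": f"gwas_cs_{k}",
                    "variant_id": str(region["id"].iloc[j]),
                    "lbf": float(lbf[j]),
                    "pip": float(pip[j]),
                    "causal_variant": causal,
                    "shared_with_molqtl": causal in set(causal_pool),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class Cohort:
    """Everything one synthetic run produces, plus its ground truth."""

    config: SimConfig
    dosages: pd.DataFrame
    variant_table: pd.DataFrame
    expression: pd.DataFrame
    accessibility: pd.DataFrame
    covariates: pd.DataFrame
    gene_table: pd.DataFrame
    peak_table: pd.DataFrame
    segmentation: pd.DataFrame
    gene_model: pd.DataFrame
    variant_scores: pd.DataFrame
    gwas_credsets: pd.DataFrame
    truth: CohortTruth


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a full cohort; ``seed`` overrides ``config.seed``."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dosages, variant_table = simulate_genotypes(config, rng)
    truth = make_truth(config, variant_table, rng)
    covariates = simulate_covariates(config, rng)
    expression, accessibility, covariates = simulate_phenotypes(
        dosages, config, truth, rng, covariates
    )
    gene_table, peak_table, segmentation, gene_model = emit_features(config, truth, rng)
    variant_scores = emit_variant_scores(truth, variant_table, peak_table, config, rng)
    gwas_credsets = emit_gwas_credsets(truth, variant_table, dosages, config, rng)
    return Cohort(
        config=config,
        dosages=dosages,
        variant_table=variant_table,
        expression=expression,
        accessibility=accessibility,
        covariates=covariates,
        gene_table=gene_table,
        peak_table=peak_table,
        segmentation=segmentation,
        gene_model=gene_model,
        variant_scores=variant_scores,
        gwas_credsets=gwas_credsets,
        truth=truth,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> list[Path]:
    """Write every table of the cohort under ``out_dir``: genotypes as a
    minimal VCF, features as BED, segmentation as BED4, phenotypes and
    scores as TSV, truth and config as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    p = out / "genotypes.vcf"
    write_vcf_lite(cohort.variant_table, cohort.dosages, p)
    paths.append(p)

    genes_bed = cohort.gene_table.rename(columns={"id": "name"})[
        ["chrom", "start", "end", "name", "strand"]
    ].assign(score=0)[["chrom", "start", "end", "name", "score", "strand"]]
    p = out / "genes.bed"
    write_bed(genes_bed, p)
    paths.append(p)

    peaks_bed = cohort.peak_table.rename(columns={"id": "name"})[
        ["chrom", "start", "end", "name"]
    ]
    p = out / "peaks.bed"
    write_bed(peaks_bed, p)
    paths.append(p)

    p = out / "chromatin_states.bed"
    cohort.segmentation.to_csv(p, sep="\t", header=False, index=False)
    paths.append(p)

    for name, df in (
        ("expression.tsv", cohort.expression),
        ("accessibility.tsv", cohort.accessibility),
        ("covariates.tsv", cohort.covariates),
        ("variant_scores.tsv", cohort.variant_scores),
        ("gwas_credsets.tsv", cohort.gwas_credsets),
        ("variants.tsv", cohort.variant_table),
    ):
        p = out / name
        df.to_csv(p, sep="\t", index=name in ("expression.tsv", "accessibility.tsv", "covariates.tsv"))
        paths.append(p)

    p = out / "truth.json"
    cohort.truth.to_json(p)
    paths.append(p)
    p = out / "sim_config.json"
    p.write_text(json.dumps(asdict(cohort.config), indent=1))
    paths.append(p)
    return paths
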