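"""Enrichment machinery: Fisher 2x2 tests, exact binomial tests, binomial
GLMs with cluster-robust (sandwich) errors, chromosome-stratified
permutation nulls, Benjamini-Hochberg correction and rank-test wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

Z95 = 1.959963984540054


@dataclass
class EnrichmentResult:
    comparison: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    p_adj: float | None = None
    method: str = "fisher"
    n: int = 0
    flagged: bool = False  # e.g. separation in a GLM

    def __post_init__(self) -> None:
        if not np.isnan(self.ci_low) and not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI does not bracket the odds ratio")


def fisher_2x2(a: int, b: int, c: int, d: int, comparison: str = "") -> EnrichmentResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    OR = (a/b)/(c/d); the p-value is the exact two-sided hypergeometric
    probability; the 95% CI is Woolf (log-OR +/- 1.96 SE with
    SE = sqrt(1/a + 1/b + 1/c + 1/d)).  A Haldane 0.5 correction is applied
    to the OR and CI when any cell is zero.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("a margin of the table is zero")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if (cells == 0).any():
        cells = cells + 0.5
    aa, bb, cc, dd = cells
    or_ = (aa / bb) / (cc / dd)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo, hi = np.exp(np.log(or_) - Z95 * se), np.exp(np.log(or_) + Z95 * se)
    return EnrichmentResult(
        comparison=comparison,
        odds_ratio=float(or_),
        ci_low=float(lo),
        ci_high=float(hi),
        p=float(p),
        method="fisher",
        n=int(a + b + c + d),
    )


def binom_test_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test by minimum-likelihood summation."""
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    return float(stats.binomtest(k, n, p0).pvalue)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def glm_enrichment(
    outcome: np.ndarray,
    class_labels: np.ndarray,
    cluster_ids: np.ndarray,
    covariates: pd.DataFrame | None = None,
    reference: str | None = None,
) -> list[EnrichmentResult]:
    """Binomial GLM (logit link) of a binary outcome on a class predictor
    with locus-clustered robust standard errors.

    Returns one EnrichmentResult per non-reference class level, OR =
    exp(coefficient) with a Wald CI from the cluster-robust (sandwich)
    covariance; BH adjustment across the family of class comparisons.
    Coefficients with |estimate| > 15 are flagged as separation and their
    CI suppressed.
    """
    y = np.asarray(outcome, dtype=float)
    labels = pd.Series(class_labels, dtype="object")
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 class levels")
    ref = reference if reference is not None else levels[0]
    others = [lv for lv in levels if lv != ref]

    X = pd.get_dummies(labels, drop_first=False)[others].astype(float)
    if covariates is not None:
        X = pd.concat([X.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    fit = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster_ids)})

    results = []
    raw_p = []
    for lv in others:
        coef = float(fit.params[lv])
        se = float(fit.bse[lv])
        p = float(fit.pvalues[lv])
        flagged = abs(coef) > 15
        if flagged:
            lo = hi = np.nan
        else:
            lo, hi = np.exp(coef - Z95 * se), np.exp(coef + Z95 * se)
        results.append(
            EnrichmentResult(
                comparison=f"{lv}_vs_{ref}",
                odds_ratio=float(np.exp(coef)),
                ci_low=float(lo),
                ci_high=float(hi),
                p=p,
                method="glm",
                n=len(y),
                flagged=flagged,
            )
        )
        raw_p.append(p)
    for res, padj in zip(results, bh_adjust(np.array(raw_p))):
        res.p_adj = float(padj)
    return results


@dataclass
class PermutationNull:
    """One class's chromosome-stratified binomial permutation null."""

    comparison: str
    observed: float
    p_one_sided: float
    n_perm: int
    at_floor: bool  # zero permuted statistics reached the observed value
    background_rates: dict[str, float] = field(default_factory=dict)

    def report_p(self) -> str:
        """The paper-style reporting string: the floor prints as an upper
        bound."""
        if self.at_floor:
            return f"< {1.0 / self.n_perm:.0e}"
        return f"{self.p_one_sided:.3g}"


def permutation_enrichment(
    hits: np.ndarray,
    callable_sizes: np.ndarray,
    chroms: np.ndarray,
    class_labels: np.ndarray,
    background_mask: np.ndarray,
    n_perm: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, PermutationNull]:
    """Chromosome-stratified permutation null for per-class hit fractions.

    Each credible set i carries h_i hits out of m_i callable variants.
    Background hit rates are estimated per chromosome from the background
    CSs (pooled fallback where a chromosome has none); each permutation
    redraws h_i* ~ Binomial(m_i, rate(chrom_i)) for every CS in the class
    and the statistic is the mean hit fraction.  p = (1 + #{stat* >=
    observed}) / (n_perm + 1), so the floor is 1/(n_perm + 1).
    """
    h = np.asarray(hits, dtype=float)
    m = np.asarray(callable_sizes, dtype=float)
    if (m < 1).any():
        raise ValueError("every CS needs at least one callable variant")
    chroms = np.asarray(chroms)
    labels = np.asarray(class_labels)
    bg = np.asarray(background_mask, dtype=bool)
    rng = rng if rng is not None else np.random.default_rng(seed)

    pooled_rate = h[bg].sum() / m[bg].sum() if bg.any() else h.sum() / m.sum()
    rates: dict[str, float] = {}
    for chrom in np.unique(chroms):
        sel = bg & (chroms == chrom)
        rates[str(chrom)] = float(h[sel].sum() / m[sel].sum()) if sel.any() else float(pooled_rate)

    out: dict[str, PermutationNull] = {}
    for cls in np.unique(labels[~bg]):
        sel = labels == cls
        if not sel.any():
            continue
        m_c = m[sel]
        rate_c = np.array([rates[str(ch)] for ch in chroms[sel]])
        observed = float(np.mean(h[sel] / m_c))
        # vectorized: n_perm x k binomial draws, chunked to bound memory
        exceed = 0
        chunk = max(1, int(5e6 // max(1, len(m_c))))
        done = 0
        while done < n_perm:
            take = min(chunk, n_perm - done)
            draws = rng.binomial(
                m_c.astype(int)[None, :], rate_c[None, :], size=(take, len(m_c))
            )
            stat = (draws / m_c[None, :]).mean(axis=1)
            exceed += int((stat >= observed - 1e-12).sum())
            done += take
        p = (1 + exceed) / (n_perm + 1)
        out[str(cls)] = PermutationNull(
            comparison=str(cls),
            observed=observed,
            p_one_sided=float(p),
            n_perm=n_perm,
            at_floor=exceed == 0,
            background_rates=rates,
        )
    return out


def proportion_chisq(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square test of independence on an r x c count table
    (no continuity correction).  Raises when an expected count is zero."""
    table = np.asarray(table, dtype=float)
    expected = stats.contingency.expected_freq(table)
    if (expected <= 0).any():
        raise ValueError("zero expected cell; collapse sparse categories first")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) with normal approximation
    and tie correction above n = 50, exact below."""
    n = len(x) + len(y)
    method = "asymptotic" if n > 50 else "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float]:
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def tf_family_enrichment(
    hit_table: pd.DataFrame, min_hits: int = 10
) -> pd.DataFrame:
    """Per-TF-family Fisher enrichment of motif-disrupting variants in
    promoter vs cis-CRE peaks.

    ``hit_table`` needs one row per (variant, family) hit candidate with
    columns variant_id, family, annotation ('promoter' | 'cis-CRE') and a
    boolean ``hit``; variants are the unit (each counted at most once per
    family) and families with fewer than ``min_hits`` hits are excluded.
    """
    dedup = hit_table.drop_duplicates(["variant_id", "family"])
    rows = []
    raw_p = []
    for family, grp in dedup.groupby("family"):
        n_hits = int(grp["hit"].sum())
        if n_hits < min_hits:
            continue
        a = int(((grp["hit"]) & (grp["annotation"] == "promoter")).sum())
        b = int(((grp["hit"]) & (grp["annotation"] == "cis-CRE")).sum())
        c = int(((~grp["hit"]) & (grp["annotation"] == "promoter")).sum())
        d = int(((~grp["hit"]) & (grp["annotation"] == "cis-CRE")).sum())
        try:
            res = fisher_2x2(a, b, c, d, comparison=str(family))
        except ValueError:
            continue
        rows.append(res)
        raw_p.append(res.p)
    for res, padj in zip(rows, bh_adjust(np.array(raw_p))):
        res.p_adj = float(padj)
    return pd.DataFrame(
        [
            {
                "family": r.comparison,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "p_adj": r.p_adj,
            }
            for r in rows
        ]
    )
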