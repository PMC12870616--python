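"""Membership-based intersection of QTL credible sets with sequence-model
variant scores, plus concordance analyses.

The unit is an *incidence*: one row per credible set (or colocalized CS
pair) for QTL-containing groups, and one row per variant for standalone
score-significant variants found in no CS.  A CS counts as score-containing
iff at least one member variant is score-significant.  The seven groups are
mutually exclusive and exhaustive over units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import CredibleSet

GROUPS = [
    "caQTL_only",
    "caQTL_eQTL",
    "chrombpnet_only",
    "chrombpnet_caQTL_eQTL",
    "chrombpnet_caQTL",
    "eQTL_only",
    "eQTL_chrombpnet",
]


def membership_groups(
    eqtl_css: list[CredibleSet],
    caqtl_css: list[CredibleSet],
    coloc_pairs: list[tuple[str, str]],
    significant_score_variants: set[str],
) -> pd.DataFrame:
    """Assign each caQTL CS, eQTL CS, colocalized pair and orphan scored
    variant to exactly one of the seven intersection groups.

    ``coloc_pairs`` holds (eqtl_cs_id, caqtl_cs_id) pairs called shared; a
    pair forms a single unit whose score membership is evaluated over the
    union of both CSs' variants.
    """
    eqtl_by_id = {cs.cs_id: cs for cs in eqtl_css}
    caqtl_by_id = {cs.cs_id: cs for cs in caqtl_css}
    paired_e = {e for e, _ in coloc_pairs}
    paired_c = {c for _, c in coloc_pairs}

    rows = []
    cs_variants: set[str] = set()
    for cs in eqtl_css + caqtl_css:
        cs_variants |= set(cs.variant_ids)

    for e_id, c_id in coloc_pairs:
        members = set(eqtl_by_id[e_id].variant_ids) | set(caqtl_by_id[c_id].variant_ids)
        has_score = bool(members & significant_score_variants)
        group = "chrombpnet_caQTL_eQTL" if has_score else "caQTL_eQTL"
        rows.append((f"pair:{e_id}|{c_id}", group, e_id, c_id, None))

    for cs in caqtl_css:
        if cs.cs_id in paired_c:
            continue
        has_score = bool(set(cs.variant_ids) & significant_score_variants)
        group = "chrombpnet_caQTL" if has_score else "caQTL_only"
        rows.append((f"cs:{cs.cs_id}", group, None, cs.cs_id, None))

    for cs in eqtl_css:
        if cs.cs_id in paired_e:
            continue
        has_score = bool(set(cs.variant_ids) & significant_score_variants)
        group = "eQTL_chrombpnet" if has_score else "eQTL_only"
        rows.append((f"cs:{cs.cs_id}", group, cs.cs_id, None, None))

    for vid in sorted(significant_score_variants - cs_variants):
        rows.append((f"variant:{vid}", "chrombpnet_only", None, None, vid))

    out = pd.DataFrame(
        rows, columns=["unit_id", "group", "eqtl_cs", "caqtl_cs", "variant_id"]
    )
    if out["unit_id"].duplicated().any():
        raise AssertionError("membership groups are not a partition of units")
    return out


DEFAULT_MAF_EDGES = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


def stratify_groups(
    groups: pd.DataFrame,
    unit_variants: dict[str, list[str]],
    variant_table: pd.DataFrame,
    variant_annotation: dict[str, str],
    caqtl_categories: dict[str, str],
    maf_edges: tuple[float, ...] = DEFAULT_MAF_EDGES,
) -> pd.DataFrame:
    """Stacked proportions per group over MAF bins, peak annotation
    ({promoter, cis-CRE, non-peak}) and in-peak caQTL category ({C1, C2}).

    ``unit_variants`` maps each unit_id to the variants it contributes;
    ``variant_annotation`` maps variant -> peak annotation;
    ``caqtl_categories`` maps variant -> C1/C2/C3.  Proportions sum to 1
    within each (group, axis).
    """
    maf = variant_table.set_index("id")["maf"]
    rows = []
    for group, grp in groups.groupby("group"):
        variants: list[str] = []
        for uid in grp["unit_id"]:
            variants.extend(unit_variants.get(uid, []))
        if not variants:
            continue
        mafs = maf.loc[variants].to_numpy()
        binned = np.clip(
            np.searchsorted(maf_edges, mafs, side="right") - 1, 0, len(maf_edges) - 2
        )
        for b in range(len(maf_edges) - 1):
            rows.append(
                (group, "maf", f"[{maf_edges[b]},{maf_edges[b + 1]})",
                 float((binned == b).mean()))
            )
        annos = pd.Series([variant_annotation.get(v, "non-peak") for v in variants])
        for label in ("promoter", "cis-CRE", "non-peak"):
            rows.append((group, "annotation", label, float((annos == label).mean())))
        cats = pd.Series([caqtl_categories.get(v) for v in variants])
        in_peak = cats.isin(["C1", "C2"])
        if in_peak.any():
            for label in ("C1", "C2"):
                rows.append(
                    (group, "caqtl_category", label,
                     float((cats[in_peak] == label).mean()))
                )
    return pd.DataFrame(rows, columns=["group", "axis", "bin", "proportion"])


def harmonize_alleles(
    scores: pd.DataFrame, assocs: pd.DataFrame
) -> pd.DataFrame:
    """Join sequence-model scores to association records on shared SNPs,
    orienting both effects ALT/REF identically.

    Optional allele columns (ref/alt on both sides) trigger orientation
    checks: a swapped pair flips the association beta; an irreconcilable
    pair is excluded.  Returns columns variant_id, log_afc, beta plus any
    significance flags present.
    """
    merged = scores.merge(assocs, on="variant_id", suffixes=("_score", "_qtl"))
    if {"ref_score", "alt_score", "ref_qtl", "alt_qtl"} <= set(merged.columns):
        same = (merged["ref_score"] == merged["ref_qtl"]) & (
            merged["alt_score"] == merged["alt_qtl"]
        )
        flipped = (merged["ref_score"] == merged["alt_qtl"]) & (
            merged["alt_score"] == merged["ref_qtl"]
        )
        merged.loc[flipped, "beta"] = -merged.loc[flipped, "beta"]
        merged = merged[same | flipped]
    return merged


def effect_concordance(
    scores: pd.DataFrame,
    caqtl_records: pd.DataFrame,
    caqtl_categories: dict[str, str],
    score_sig: set[str],
    caqtl_sig: set[str],
) -> dict[str, dict[str, float]]:
    """Pearson correlation between predicted allelic log fold-change and the
    empirical caQTL beta, per joint-significance class.

    The comparison is restricted to in-peak (C1/C2) caQTL variants, since
    sequence models only see local regulatory effects.  Classes:
    both_significant, score_only, caqtl_only.
    """
    merged = harmonize_alleles(scores, caqtl_records)
    cats = merged["variant_id"].map(caqtl_categories)
    merged = merged[cats.isin(["C1", "C2"])]

    in_score = merged["variant_id"].isin(score_sig)
    in_caqtl = merged["variant_id"].isin(caqtl_sig)
    classes = {
        "both_significant": merged[in_score & in_caqtl],
        "score_only": merged[in_score & ~in_caqtl],
        "caqtl_only": merged[~in_score & in_caqtl],
    }
    out = {}
    for name, df in classes.items():
        if len(df) >= 3:
            r = float(np.corrcoef(df["log_afc"], df["beta"])[0, 1])
            out[name] = {"r": r, "r2": r * r, "n": int(len(df))}
        else:
            out[name] = {"r": np.nan, "r2": np.nan, "n": int(len(df))}
    return out


@dataclass(frozen=True)
class CoverageComparison:
    t_statistic: float
    p_value: float
    mean_group1: float
    mean_group2: float
    n1: int
    n2: int


def coverage_compare(
    coverage_specific: np.ndarray, coverage_shared: np.ndarray, equal_var: bool = False
) -> CoverageComparison:
    """Two-sided two-sample t-test comparing peak read coverage between
    score-specific variants and score variants shared with molQTLs (Welch by
    default)."""
    a = np.asarray(coverage_specific, dtype=float)
    b = np.asarray(coverage_shared, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return CoverageComparison(
        t_statistic=float(t),
        p_value=float(p),
        mean_group1=float(a.mean()),
        mean_group2=float(b.mean()),
        n1=len(a),
        n2=len(b),
    )
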