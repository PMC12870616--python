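"""Credible-set level classification and annotation rules.

caQTL variants are classified by where they fall relative to peaks (C1 =
inside the associated caPeak, C2 = inside a different peak, C3 = outside all
peaks) and each CS inherits a single label through the hierarchy C1 > C2 >
C3.  Genomic-region and chromatin-state labels are assigned per CS by
majority vote across member variants with fixed priority tie-breaks.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .intervals import assign_points
from .model import CredibleSet

REGION_PRIORITY = [
    "coding",
    "fiveUTR",
    "threeUTR",
    "spliceSite",
    "promoter",
    "intron",
    "intergenic",
]

STATE_PRIORITY = [
    "Promoter",
    "Enhancer_active",
    "Enhancer_weak",
    "Transcribed",
    "Repressed_polycomb",
    "ZNF_Het_Quies",
]

CS_CATEGORY_LABELS = ["in_caPeak", "in_other_Peak", "no_Peak_overlap"]


def _variant_in_peak(pos: int, start: int, end: int) -> bool:
    # overlap = half-open containment of the variant position
    return start <= pos < end


def classify_caqtl_variant(
    pos: int, ca_peak_id: str, peaks: pd.DataFrame
) -> str:
    """C1 if the variant lies in its associated caPeak, C2 if in any other
    peak, C3 otherwise.  ``peaks`` needs columns id/start/end (one
    chromosome's peaks, or pre-filtered to the variant's chromosome)."""
    if ca_peak_id not in set(peaks["id"]):
        raise ValueError(f"associated caPeak {ca_peak_id} absent from peak set")
    in_peak = peaks[
        (peaks["start"] <= pos) & (pos < peaks["end"])
    ]
    if (in_peak["id"] == ca_peak_id).any():
        return "C1"
    if len(in_peak) > 0:
        return "C2"
    return "C3"


def classify_caqtl_cs(member_labels: list[str]) -> str:
    """Collapse member variant labels through the hierarchy C1 > C2 > C3."""
    if not member_labels:
        raise ValueError("empty label list")
    if "C1" in member_labels:
        return "in_caPeak"
    if "C2" in member_labels:
        return "in_other_Peak"
    return "no_Peak_overlap"


def _majority_vote(labels: list[str], priority: list[str]) -> str:
    if not labels:
        raise ValueError("cannot vote over an empty credible set")
    counts = Counter(labels)
    top = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == top]
    for lab in priority:
        if lab in tied:
            return lab
    raise ValueError(f"labels {tied} outside the known vocabulary")


def annotate_cs_region(member_labels: list[str]) -> str:
    """Single genomic-region label per CS: majority vote across variants,
    ties broken by coding > fiveUTR > threeUTR > spliceSite > promoter >
    intron > intergenic."""
    return _majority_vote(member_labels, REGION_PRIORITY)


def annotate_cs_chromstate(
    positions: np.ndarray, chroms: np.ndarray, segmentation: pd.DataFrame
) -> str:
    """Chromatin-state supergroup per CS: majority vote over the segment
    labels at each member variant, ties broken by the state priority."""
    labels = assign_points(np.asarray(positions), np.asarray(chroms), segmentation)
    return _majority_vote(list(labels), STATE_PRIORITY)


def assign_region_labels(
    positions: np.ndarray, chroms: np.ndarray, gene_model: pd.DataFrame
) -> np.ndarray:
    """Per-variant genomic-region labels from a gene-model interval table
    (columns chrom/start/end/label).  Where intervals overlap, the highest
    priority label wins; positions in no interval are intergenic."""
    rank = {lab: i for i, lab in enumerate(REGION_PRIORITY)}
    out = np.full(len(positions), "intergenic", dtype=object)
    for chrom in np.unique(chroms):
        seg = gene_model[gene_model["chrom"] == chrom]
        sel = np.flatnonzero(chroms == chrom)
        for row in seg.itertuples(index=False):
            hit = sel[(positions[sel] >= row.start) & (positions[sel] < row.end)]
            for i in hit:
                if rank[row.label] < rank[out[i]]:
                    out[i] = row.label
    return out


def cs_feature_distance(positions: np.ndarray, anchor: int) -> tuple[float, float]:
    """Mean absolute distance between CS member variants and the feature
    anchor (TSS or summit), plus its log2(distance + 1) transform."""
    mean_d = float(np.mean(np.abs(np.asarray(positions, dtype=float) - anchor)))
    return mean_d, float(np.log2(mean_d + 1.0))


def filter_cs_size_quantile(
    css: list[CredibleSet], quantile: float = 0.75
) -> list[CredibleSet]:
    """Retain CSs whose size is at or below the per-QTL-type size quantile
    (linear-interpolation quantile; ties at the threshold retained)."""
    if not css:
        return []
    thresholds: dict[str, float] = {}
    for qtl_type in {cs.qtl_type for cs in css}:
        sizes = [cs.size for cs in css if cs.qtl_type == qtl_type]
        thresholds[qtl_type] = float(np.quantile(sizes, quantile))
    return [cs for cs in css if cs.size <= thresholds[cs.qtl_type]]


def annotate_credible_sets(
    css: list[CredibleSet],
    variant_table: pd.DataFrame,
    peaks: pd.DataFrame,
    gene_model: pd.DataFrame,
    segmentation: pd.DataFrame,
    anchors: dict[str, int],
) -> pd.DataFrame:
    """Full CS annotation table: caQTL category, region label, chromatin
    state, and distance to the associated feature anchor.

    ``anchors`` maps feature_id to TSS/summit position; ``variant_table``
    needs id/chrom/pos.
    """
    vt = variant_table.set_index("id")
    rows = []
    for cs in css:
        pos = vt.loc[cs.variant_ids, "pos"].to_numpy()
        chrom = vt.loc[cs.variant_ids, "chrom"].to_numpy()
        if cs.qtl_type == "caQTL":
            labels = [
                classify_caqtl_variant(
                    int(p), cs.feature_id, peaks[peaks["chrom"] == c]
                )
                for p, c in zip(pos, chrom)
            ]
            category = classify_caqtl_cs(labels)
        else:
            category = ""
        region = annotate_cs_region(list(assign_region_labels(pos, chrom, gene_model)))
        state = annotate_cs_chromstate(pos, chrom, segmentation)
        mean_d, log2_d = cs_feature_distance(pos, anchors[cs.feature_id])
        rows.append(
            (cs.cs_id, cs.qtl_type, category, region, state, mean_d, log2_d)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cs_id",
            "qtl_type",
            "category",
            "region_label",
            "state_label",
            "mean_distance",
            "log2_distance",
        ],
    )
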