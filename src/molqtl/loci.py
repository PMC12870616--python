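"""Fine-mapping region construction and locus collapsing.

Regions are built as windows around conditionally independent lead variants
and merged until no two regions share a variant.  Credible sets are later
collapsed into loci: nodes are CS intervals (min to max member position),
edges connect pairs with base-pair Jaccard >= a threshold, and loci are the
connected components of that graph.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .model import CredibleSet, FinemapRegion, GenomicInterval, Locus

# The extended MHC is excluded from region building; a slightly narrower
# interval is the default for the GWAS-enrichment background.
MHC_EXCLUSION_MOLQTL = GenomicInterval("chr6", 25_000_000, 36_000_000)
MHC_EXCLUSION_GWAS = GenomicInterval("chr6", 25_000_000, 34_000_000)

DEFAULT_TARGET_BINS = ("1", "2", "3", ">=4")


def merge_finemap_regions(
    leads: pd.DataFrame,
    window: int,
    variant_table: pd.DataFrame,
    exclusions: list[GenomicInterval] | None = None,
    min_variants: int = 100,
) -> list[FinemapRegion]:
    """Build disjoint fine-mapping regions of +/- ``window`` bp around each
    lead, iteratively merged until no two regions share a variant.

    Regions overlapping an exclusion interval are dropped, as are regions
    holding fewer than ``min_variants`` variants.  ``leads`` needs columns
    id/chrom/pos and must be position-sorted within chromosome.
    """
    exclusions = exclusions if exclusions is not None else [MHC_EXCLUSION_MOLQTL]
    out: list[FinemapRegion] = []
    var_sorted = variant_table.sort_values(["chrom", "pos"])
    counter = 0
    for chrom, chrom_leads in leads.groupby("chrom", sort=False):
        pos = chrom_leads["pos"].to_numpy()
        ids = chrom_leads["id"].to_numpy()
        if not np.all(np.diff(pos) >= 0):
            raise ValueError("leads must be sorted by position within chromosome")
        vt = var_sorted[var_sorted["chrom"] == chrom]
        vpos = vt["pos"].to_numpy()
        vids = vt["id"].to_numpy()

        # Two windows share a variant iff some variant sits in both, which
        # for windows on a common grid reduces to checking each gap for an
        # intervening variant-free stretch.  Merge greedily left to right.
        groups: list[list[int]] = [[0]] if len(pos) else []
        for i in range(1, len(pos)):
            prev = groups[-1]
            prev_end = max(pos[j] for j in prev) + window
            cur_start = pos[i] - window
            shared = (vpos >= cur_start) & (vpos <= prev_end)
            if cur_start <= prev_end and shared.any():
                prev.append(i)
            else:
                groups.append([i])
        for grp in groups:
            start = int(min(pos[j] for j in grp) - window)
            end = int(max(pos[j] for j in grp) + window + 1)
            start = max(start, 0)
            region_iv = GenomicInterval(chrom, start, end)
            if any(region_iv.overlaps(ex) for ex in exclusions):
                continue
            sel = (vpos >= start) & (vpos < end)
            if sel.sum() < min_variants:
                continue
            counter += 1
            out.append(
                FinemapRegion(
                    region_id=f"region_{counter}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    variant_ids=[str(v) for v in vids[sel]],
                    lead_ids=[str(ids[j]) for j in grp],
                )
            )
    return out


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    """Base-pair Jaccard index |a n b| / |a u b|; 0 across chromosomes.

    Zero-length intervals (single-variant CSs) have Jaccard 1 with an
    identical interval and 0 with anything else.
    """
    if a.chrom != b.chrom:
        return 0.0
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = len(a) + len(b) - inter
    if union == 0:
        return 1.0 if (a.start, a.end) == (b.start, b.end) else 0.0
    return inter / union


def cs_interval(cs: CredibleSet, variant_table: pd.DataFrame) -> GenomicInterval:
    """CS span from the minimum and maximum member variant positions."""
    vt = variant_table.set_index("id")
    pos = vt.loc[cs.variant_ids, "pos"].to_numpy()
    chroms = vt.loc[cs.variant_ids, "chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"CS {cs.cs_id} spans multiple chromosomes")
    return GenomicInterval(str(chroms[0]), int(pos.min()), int(pos.max()))


def build_loci(
    css: list[CredibleSet],
    variant_table: pd.DataFrame,
    threshold: float = 0.3,
) -> list[Locus]:
    """Group CSs into loci: connected components of the graph whose edges
    join CS pairs with interval Jaccard >= ``threshold``.  Singleton CSs
    form singleton loci."""
    intervals = {cs.cs_id: cs_interval(cs, variant_table) for cs in css}
    graph = nx.Graph()
    graph.add_nodes_from(intervals)
    ids = list(intervals)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if jaccard(intervals[ids[i]], intervals[ids[j]]) >= threshold:
                graph.add_edge(ids[i], ids[j])
    loci = []
    for k, comp in enumerate(sorted(nx.connected_components(graph), key=sorted), start=1):
        members = sorted(comp)
        chrom = intervals[members[0]].chrom
        start = min(intervals[m].start for m in members)
        end = max(intervals[m].end for m in members)
        loci.append(
            Locus(
                locus_id=f"locus_{k}",
                cs_ids=members,
                interval=GenomicInterval(chrom, start, end),
            )
        )
    return loci


def locus_target_multiplicity(
    loci: list[Locus],
    cs_to_feature: dict[str, str],
    bins: tuple[str, ...] = DEFAULT_TARGET_BINS,
) -> pd.DataFrame:
    """Per-locus count of distinct regulated features, binned {1, 2, 3, >=4}
    by default."""
    n_explicit = len(bins) - 1
    rows = []
    for locus in loci:
        count = len({cs_to_feature[c] for c in locus.cs_ids})
        label = bins[count - 1] if count <= n_explicit else bins[-1]
        locus.target_count = count
        locus.target_bin = label
        rows.append((locus.locus_id, count, label))
    return pd.DataFrame(rows, columns=["locus_id", "target_count", "target_bin"])
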