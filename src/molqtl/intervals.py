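"""Interval engine shared by every annotation step.

All intervals are 0-based half-open.  The workloads here are small (at most
tens of thousands of records), so the join uses a per-chromosome sort plus
binary search rather than an interval tree; a quadratic oracle checks it in
the test suite.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd


def overlap(a: pd.DataFrame, b: pd.DataFrame) -> list[tuple[int, int]]:
    """All pairs (i, j) such that a.iloc[i] and b.iloc[j] overlap.

    Both frames need columns ``chrom``, ``start``, ``end`` (half-open).
    Returned indices are positional.  Touching intervals ([0,10) vs [10,20))
    do not overlap.
    """
    for name, df in (("a", a), ("b", b)):
        if not {"chrom", "start", "end"}.issubset(df.columns):
            raise ValueError(f"frame {name} needs chrom/start/end columns")

    by_chrom: dict[str, list[int]] = defaultdict(list)
    for j, chrom in enumerate(b["chrom"].to_numpy()):
        by_chrom[chrom].append(j)

    pairs: list[tuple[int, int]] = []
    a_chrom = a["chrom"].to_numpy()
    a_start = a["start"].to_numpy()
    a_end = a["end"].to_numpy()
    b_start_all = b["start"].to_numpy()
    b_end_all = b["end"].to_numpy()

    # Per chromosome, sort B by start; for each A interval every overlapping B
    # record has start < a.end, found by one binary search, then filtered on
    # end > a.start.
    prepared: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, idx in by_chrom.items():
        idx_arr = np.asarray(idx)
        order = np.argsort(b_start_all[idx_arr], kind="stable")
        idx_sorted = idx_arr[order]
        prepared[chrom] = (
            b_start_all[idx_sorted],
            b_end_all[idx_sorted],
            idx_sorted,
        )

    for i in range(len(a)):
        got = prepared.get(a_chrom[i])
        if got is None:
            continue
        starts, ends, idx_sorted = got
        hi = np.searchsorted(starts, a_end[i], side="left")
        if hi == 0:
            continue
        mask = ends[:hi] > a_start[i]
        for j in idx_sorted[:hi][mask]:
            pairs.append((i, int(j)))
    return pairs


def assign_points(positions: np.ndarray, chroms: np.ndarray, segments: pd.DataFrame) -> np.ndarray:
    """Label each point by the segment [start, end) that contains it.

    ``segments`` needs columns chrom/start/end/label and must tile each
    chromosome without overlap.  Returns an object array of labels; a point
    outside every segment raises.
    """
    labels = np.empty(len(positions), dtype=object)
    for chrom in np.unique(chroms):
        seg = segments[segments["chrom"] == chrom].sort_values("start")
        if seg.empty:
            raise ValueError(f"no segmentation for chromosome {chrom}")
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        seg_labels = seg["label"].to_numpy()
        sel = chroms == chrom
        pos = positions[sel]
        k = np.searchsorted(starts, pos, side="right") - 1
        bad = (k < 0) | (pos >= ends[np.clip(k, 0, len(ends) - 1)])
        if bad.any():
            p = pos[bad][0]
            raise ValueError(f"position {chrom}:{p} outside the segmentation")
        labels[sel] = seg_labels[k]
    return labels
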