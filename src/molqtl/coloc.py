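"""Five-hypothesis colocalization from per-variant log Bayes factors.

Given two traits' per-variant log Bayes factors over a shared variant index,
the posterior mass is split over H0 (neither trait associated), H1/H2 (one
trait only), H3 (two distinct causal variants) and H4 (one shared causal
variant) using per-variant prior probabilities p1, p2, p12.  With
S1 = sum_i exp(lbf1_i), S2 = sum_j exp(lbf2_j), S12 = sum_i exp(lbf1_i +
lbf2_i), the unnormalized hypothesis weights are

    (1,  p1*S1,  p2*S2,  p1*p2*(S1*S2 - S12),  p12*S12)

and everything is evaluated in log space with log-sum-exp for stability.
A single-variant fallback applies the same formula with H3 mass zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities of association (p1, p2) and of a
    shared causal variant (p12)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            warnings.warn("p12 exceeds min(p1, p2); priors are unusual", stacklevel=2)


@dataclass
class ColocResult:
    cs1: str
    cs2: str
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    per_snp_h4: pd.Series = field(repr=False, default=None)

    @property
    def shared(self) -> bool:
        return self.pp_h4 > 0.5

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


def single_snp_h4(lbf1: pd.Series, lbf2: pd.Series) -> pd.Series:
    """Per-variant posterior of being the shared causal variant under H4:
    the softmax of the elementwise lbf sum."""
    if not lbf1.index.equals(lbf2.index):
        raise ValueError("lbf vectors must share the same variant index")
    s = lbf1.to_numpy(dtype=float) + lbf2.to_numpy(dtype=float)
    s = s - s.max()
    w = np.exp(s - logsumexp(s))
    return pd.Series(w, index=lbf1.index)


def coloc_from_lbf(
    lbf1: pd.Series,
    lbf2: pd.Series,
    priors: ColocPriors | None = None,
    min_shared: int = 1,
    cs1: str = "trait1",
    cs2: str = "trait2",
) -> ColocResult | None:
    """Colocalize two signals from their per-variant log Bayes factors.

    Returns None (with a logged reason) when fewer than ``min_shared``
    variants are shared; raises on mismatched variant indexes.
    """
    priors = priors or ColocPriors()
    if not lbf1.index.equals(lbf2.index):
        raise ValueError("lbf vectors must share the same variant index")
    n = len(lbf1)
    if n < min_shared:
        logger.info("skipping %s vs %s: %d shared variants < %d", cs1, cs2, n, min_shared)
        return None

    a1 = lbf1.to_numpy(dtype=float)
    a2 = lbf2.to_numpy(dtype=float)
    s1 = logsumexp(a1)
    s2 = logsumexp(a2)
    s12 = logsumexp(a1 + a2)

    log_w = np.empty(5)
    log_w[0] = 0.0
    log_w[1] = np.log(priors.p1) + s1
    log_w[2] = np.log(priors.p2) + s2
    # H3 mass = S1*S2 - S12, computed as exp(s1+s2) * (1 - exp(s12-s1-s2))
    diff = s12 - (s1 + s2)
    if n == 1 or diff >= 0.0:
        log_w[3] = -np.inf
    else:
        log_w[3] = np.log(priors.p1) + np.log(priors.p2) + s1 + s2 + np.log1p(-np.exp(diff))
    log_w[4] = np.log(priors.p12) + s12

    pp = np.exp(log_w - logsumexp(log_w))
    return ColocResult(
        cs1=cs1,
        cs2=cs2,
        pp_h0=float(pp[0]),
        pp_h1=float(pp[1]),
        pp_h2=float(pp[2]),
        pp_h3=float(pp[3]),
        pp_h4=float(pp[4]),
        per_snp_h4=single_snp_h4(lbf1, lbf2),
    )


def coloc_variant_filter(
    variants: pd.DataFrame,
    p_threshold: float = 1e-3,
    pip_threshold: float = 0.01,
    pip_rule: str = "either",
) -> pd.DataFrame:
    """Post-colocalization variant filter: nominal p below threshold in both
    traits and PIP above threshold in at least one CS (``pip_rule='both'``
    requires it in both).

    ``variants`` needs columns p_trait1, p_trait2, pip_trait1, pip_trait2.
    """
    if pip_rule not in ("either", "both"):
        raise ValueError("pip_rule must be 'either' or 'both'")
    p_ok = (variants["p_trait1"] < p_threshold) & (variants["p_trait2"] < p_threshold)
    pip1 = variants["pip_trait1"] > pip_threshold
    pip2 = variants["pip_trait2"] > pip_threshold
    pip_ok = (pip1 | pip2) if pip_rule == "either" else (pip1 & pip2)
    return variants[p_ok & pip_ok]


def collapse_coloc_loci(pairs: list[tuple[str, str]]) -> dict[tuple[str, str], str]:
    """Collapse colocalized CS pairs into locus ids: pairs sharing a CS get
    the same id (connected components over the bipartite CS graph)."""
    graph = nx.Graph()
    for cs1, cs2 in pairs:
        graph.add_edge(("t1", cs1), ("t2", cs2))
    comp_of: dict = {}
    for k, comp in enumerate(sorted(nx.connected_components(graph), key=sorted), start=1):
        for node in comp:
            comp_of[node] = f"coloc_locus_{k}"
    return {(c1, c2): comp_of[("t1", c1)] for c1, c2 in pairs}


GWAS_CLASSES = ["eQTL_only", "caQTL_only", "shared_eQTL_caQTL", "none"]


def gwas_coloc_summary(
    gwas_cs: pd.DataFrame,
    coloc_calls: pd.DataFrame,
    score_hits: pd.DataFrame,
) -> pd.DataFrame:
    """Per-trait fractions of GWAS credible sets by molQTL-colocalization
    class and by sequence-model score membership.

    Parameters
    ----------
    gwas_cs : one row per (trait, cs_id).
    coloc_calls : columns cs_id, qtl_type, shared (bool) — one row per
        GWAS-CS x molQTL colocalization attempt.
    score_hits : columns cs_id, has_score_hit (bool), hit_in_qtl_cs (bool) —
        whether the CS contains >= 1 significant scored variant, and whether
        that variant is shared with a molQTL CS.
    """
    if len(coloc_calls):
        shared = coloc_calls[coloc_calls["shared"]]
        by_cs = shared.groupby("cs_id")["qtl_type"].agg(set)
    else:
        by_cs = pd.Series(dtype=object)

    def classify(cs_id: str) -> str:
        types = by_cs.get(cs_id, set())
        if {"eQTL", "caQTL"} <= types:
            return "shared_eQTL_caQTL"
        if "eQTL" in types:
            return "eQTL_only"
        if "caQTL" in types:
            return "caQTL_only"
        return "none"

    hits = score_hits.set_index("cs_id") if len(score_hits) else pd.DataFrame()
    rows = []
    for trait, grp in gwas_cs.groupby("trait"):
        cs_ids = grp["cs_id"].unique()
        total = len(cs_ids)
        classes = pd.Series([classify(c) for c in cs_ids])
        frac = {cls: float((classes == cls).mean()) for cls in GWAS_CLASSES}
        with_hit = qtl_shared = score_specific = 0
        for c in cs_ids:
            if len(hits) and c in hits.index and bool(hits.loc[c, "has_score_hit"]):
                with_hit += 1
                if bool(hits.loc[c, "hit_in_qtl_cs"]):
                    qtl_shared += 1
                else:
                    score_specific += 1
        rows.append(
            {
                "trait": trait,
                "n_cs": total,
                **{f"frac_{cls}": frac[cls] for cls in GWAS_CLASSES},
                "frac_colocalized": 1.0 - frac["none"],
                "frac_score_hit": with_hit / total,
                "frac_score_qtl_shared": qtl_shared / total,
                "frac_score_specific": score_specific / total,
            }
        )
    return pd.DataFrame(rows)
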