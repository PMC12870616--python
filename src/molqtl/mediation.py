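"""Bidirectional causal mediation between chromatin accessibility and gene
expression.

Each colocalized variant-peak-gene triplet is evaluated under two directional
models.  With exposure E (the mediator CS's lead variant), mediator A and
outcome B:

* the secondary linkage test asks whether E is associated with B
  (likelihood ratio of B ~ E vs B ~ 1);
* the conditional independence test asks whether E carries information about
  B once A is known (B ~ A + E vs B ~ A).

Mediation A -> B predicts a significant linkage test and a *null* conditional
independence test (d-separation: E affects B only through A).  Each test
statistic is converted to a posterior through a two-groups model — Storey
pi0 plus a beta-uniform mixture fit of the p-value density — and the two
posteriors combine by product into P(A -> B).  A global FDR over a retained
set at threshold t is 1 - mean(P(A->B)); the calling threshold is stepped
down until the target global FDR is reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .qtl import residualize

LRT_CAP = 1e4  # guard for exact collinearity (RSS1 -> 0)

residualize_covariates = residualize  # phenotype correction reuses the OLS projection


def rank_inverse_normal(values: np.ndarray, c: float = 0.5) -> np.ndarray:
    """Rank-based inverse normal transform: rank r of n maps to
    Phi^-1((r - c) / (n - 2c + 1)); ties get average ranks.

    The default offset c = 0.5 gives quantiles (r - 0.5)/n; c = 0.375 (Blom)
    is also accepted.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(values) == 0:
        raise ValueError("constant vector cannot be rank-transformed")
    ranks = stats.rankdata(values, method="average")
    quantiles = (ranks - c) / (len(values) - 2 * c + 1)
    return stats.norm.ppf(quantiles)


def _rss(y: np.ndarray, X: np.ndarray | None) -> float:
    if X is None:
        r = y - y.mean()
        return float(r @ r)
    X1 = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
    r = y - X1 @ coef
    return float(r @ r)


def mediation_tests(e: np.ndarray, a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Log-likelihood-ratio statistics (linkage, conditional independence)
    for one triplet; inputs must already be residualized and transformed.

    linkage   : n * log(RSS(B ~ 1)   / RSS(B ~ E))
    condindep : n * log(RSS(B ~ A)   / RSS(B ~ A + E))

    Both are ~ chi2(1) under their nulls.  Exact collinearity is capped at
    ``LRT_CAP``.
    """
    e = np.asarray(e, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(b)
    for name, v in (("E", e), ("A", a), ("B", b)):
        if np.ptp(v) == 0:
            raise ValueError(f"zero-variance input {name}")

    def lrt(rss0: float, rss1: float) -> float:
        # RSS ratios beyond ~1e12 are numerically exact fits (collinearity)
        if rss1 <= rss0 * 1e-12:
            return LRT_CAP
        return min(n * np.log(rss0 / rss1), LRT_CAP)

    linkage = lrt(_rss(b, None), _rss(b, e[:, None]))
    condindep = lrt(_rss(b, a[:, None]), _rss(b, np.column_stack([a, e])))
    return linkage, condindep


def _fit_bum_alpha(p: np.ndarray, pi0: float) -> float:
    """MLE of the beta shape alpha in the two-groups density
    f(p) = pi0 + (1 - pi0) * alpha * p^(alpha - 1), alpha in (0, 1)."""
    if pi0 >= 1.0 - 1e-9:
        return 1.0
    logp = np.log(p)

    def nll(alpha: float) -> float:
        dens = pi0 + (1.0 - pi0) * alpha * np.exp((alpha - 1.0) * logp)
        return -np.sum(np.log(np.maximum(dens, 1e-300)))

    res = optimize.minimize_scalar(nll, bounds=(1e-3, 1.0 - 1e-6), method="bounded")
    return float(res.x)


def posterior_from_statistics(
    statistics: np.ndarray, side: str = "alternative", df: int = 1
) -> np.ndarray:
    """Posterior per test from a two-groups model over all statistics.

    P-values come from the chi-square null of the LRT; pi0 is a Storey
    estimate taken conservatively as the maximum over a lambda grid
    (including the usual lambda = 0.5), which protects the null-side
    posterior from the downward sampling noise of any single lambda.  The
    alternative density is a beta-uniform mixture; a floor of residual
    alternative weight keeps the local fdr a proper mixture quantity.
    ``side='alternative'`` returns 1 - local fdr (posterior the alternative
    holds); ``side='null'`` returns the local fdr itself (posterior the
    null holds, used for the conditional independence test).
    """
    if side not in ("alternative", "null"):
        raise ValueError("side must be 'alternative' or 'null'")
    statistics = np.asarray(statistics, dtype=float)
    if len(statistics) < 50:
        raise ValueError("need >= 50 statistics for stable mixture fitting")
    p = np.clip(stats.chi2.sf(statistics, df), 1e-300, 1.0)
    if np.ptp(p) == 0:
        warnings.warn("degenerate p-value distribution; falling back to pi0 = 1", stacklevel=2)
        lfdr = np.ones_like(p)
    else:
        lambdas = (0.2, 0.35, 0.5, 0.65, 0.8)
        pi0 = max(float(np.mean(p > lam)) / (1.0 - lam) for lam in lambdas)
        pi0 = float(np.clip(pi0, 1e-4, 1.0 - 1e-3))
        alpha = _fit_bum_alpha(p, pi0)
        dens = pi0 + (1.0 - pi0) * alpha * np.power(p, alpha - 1.0)
        lfdr = np.clip(pi0 / dens, 0.0, 1.0)
    return lfdr if side == "null" else 1.0 - lfdr


def composite_posterior(pp_linkage: np.ndarray, pp_condindep: np.ndarray) -> np.ndarray:
    """P(A -> B): product of the secondary-linkage and conditional-
    independence posteriors."""
    a = np.asarray(pp_linkage, dtype=float)
    b = np.asarray(pp_condindep, dtype=float)
    if ((a < 0) | (a > 1) | (b < 0) | (b > 1)).any():
        raise ValueError("posteriors must lie in [0, 1]")
    return a * b


@dataclass(frozen=True)
class FdrEstimate:
    """Global FDR of the retained call set: 1 - mean posterior."""

    threshold: float | None
    n_retained: int
    fdr_global: float


def global_fdr_threshold(posteriors: np.ndarray, target: float = 0.05) -> FdrEstimate:
    """Step the P(A->B) threshold down over the sorted posteriors and return
    the smallest threshold whose retained set keeps the global FDR
    (1 - mean posterior) at or below ``target``."""
    pp = np.asarray(posteriors, dtype=float)
    if ((pp < 0) | (pp > 1)).any():
        raise ValueError("posteriors must lie in [0, 1]")
    order = np.argsort(-pp, kind="stable")
    sorted_pp = pp[order]
    if len(pp) == 0:
        return FdrEstimate(None, 0, 0.0)
    cum_mean = np.cumsum(sorted_pp) / np.arange(1, len(pp) + 1)
    fdr = 1.0 - cum_mean
    # retained set at threshold t is {pp >= t}; candidate cuts sit at each
    # distinct posterior value
    ok = np.flatnonzero(fdr <= target)
    if len(ok) == 0:
        return FdrEstimate(None, 0, 0.0)
    # extend to the last index sharing the same posterior value (ties at the
    # threshold are all retained together)
    k = ok[-1]
    thr = sorted_pp[k]
    while k + 1 < len(pp) and sorted_pp[k + 1] == thr:
        k += 1
    if 1.0 - cum_mean[k] > target:
        # retaining the tie block pushed the FDR over; back off to the
        # previous distinct value
        valid = [i for i in ok if i == len(pp) - 1 or sorted_pp[i + 1] != sorted_pp[i]]
        if not valid:
            return FdrEstimate(None, 0, 0.0)
        k = valid[-1]
        thr = sorted_pp[k]
    return FdrEstimate(float(thr), int(k + 1), float(1.0 - cum_mean[k]))


def run_bidirectional(
    triplets: pd.DataFrame,
    expression: pd.DataFrame,
    accessibility: pd.DataFrame,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame,
    fdr_target: float = 0.05,
    int_offset: float = 0.5,
) -> pd.DataFrame:
    """Evaluate both mediation directions on every colocalized triplet.

    ``triplets`` needs columns locus_id, gene, peak, exposure_chrom_to_gene
    (lead variant of the caQTL CS) and exposure_gene_to_chrom (lead variant
    of the eQTL CS).  Phenotypes are covariate-residualized and rank
    inverse-normal transformed before testing; posteriors are fit per
    direction across all triplets and thresholded at the target global FDR.

    Returns one row per (triplet, direction) with the two posteriors, their
    composite P(A->B), the primary-linkage diagnostic (E -> A) and the
    significance flag.
    """
    expr = pd.DataFrame(
        residualize(expression.to_numpy(dtype=float), covariates.to_numpy(dtype=float)),
        index=expression.index,
        columns=expression.columns,
    )
    acc = pd.DataFrame(
        residualize(accessibility.to_numpy(dtype=float), covariates.to_numpy(dtype=float)),
        index=accessibility.index,
        columns=accessibility.columns,
    )
    expr = expr.apply(lambda col: rank_inverse_normal(col.to_numpy(), c=int_offset), axis=0)
    acc = acc.apply(lambda col: rank_inverse_normal(col.to_numpy(), c=int_offset), axis=0)

    rows = []
    for trip in triplets.itertuples(index=False):
        for direction in ("chrom_to_gene", "gene_to_chrom"):
            if direction == "chrom_to_gene":
                e = dosages[trip.exposure_chrom_to_gene].to_numpy(dtype=float)
                a = acc[trip.peak].to_numpy()
                b = expr[trip.gene].to_numpy()
                mediator, outcome, exposure = trip.peak, trip.gene, trip.exposure_chrom_to_gene
            else:
                e = dosages[trip.exposure_gene_to_chrom].to_numpy(dtype=float)
                a = expr[trip.gene].to_numpy()
                b = acc[trip.peak].to_numpy()
                mediator, outcome, exposure = trip.gene, trip.peak, trip.exposure_gene_to_chrom
            linkage, condindep = mediation_tests(e, a, b)
            primary, _ = mediation_tests(e, b, a)  # E -> A diagnostic
            rows.append(
                {
                    "locus_id": trip.locus_id,
                    "direction": direction,
                    "exposure": exposure,
                    "mediator": mediator,
                    "outcome": outcome,
                    "lrt_linkage": linkage,
                    "lrt_condindep": condindep,
                    "lrt_primary": primary,
                }
            )
    result = pd.DataFrame(rows)
    result["pp_linkage"] = np.nan
    result["pp_condindep"] = np.nan
    result["pp_composite"] = np.nan
    result["significant"] = False
    for direction, grp in result.groupby("direction"):
        pp_link = posterior_from_statistics(grp["lrt_linkage"].to_numpy(), side="alternative")
        pp_ci = posterior_from_statistics(grp["lrt_condindep"].to_numpy(), side="null")
        pp = composite_posterior(pp_link, pp_ci)
        est = global_fdr_threshold(pp, target=fdr_target)
        sig = np.zeros(len(grp), dtype=bool) if est.threshold is None else pp >= est.threshold
        result.loc[grp.index, "pp_linkage"] = pp_link
        result.loc[grp.index, "pp_condindep"] = pp_ci
        result.loc[grp.index, "pp_composite"] = pp
        result.loc[grp.index, "significant"] = sig
    return result


def summarize_directions(results: pd.DataFrame) -> dict:
    """Locus-collapsed summary per direction: unique significant triplets,
    mediators and targets, plus the overlap of loci significant under both
    directions."""
    out: dict = {}
    sig = results[results["significant"]]
    for direction in ("chrom_to_gene", "gene_to_chrom"):
        d = sig[sig["direction"] == direction]
        out[direction] = {
            "n_triplets": int(len(d)),
            "n_loci": int(d["locus_id"].nunique()),
            "n_mediators": int(d["mediator"].nunique()),
            "n_targets": int(d["outcome"].nunique()),
        }
    both = set(sig[sig["direction"] == "chrom_to_gene"]["locus_id"]) & set(
        sig[sig["direction"] == "gene_to_chrom"]["locus_id"]
    )
    out["loci_significant_both_directions"] = int(len(both))
    return out
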