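"""Cis-QTL linear scan and single-effect Bayes-factor fine-mapping.

These are the plumbing that connects synthetic phenotypes to credible sets:
a covariate-adjusted per-variant OLS scan within a cis window, and a
single-causal-variant fine-mapper that converts each variant's z-score into
an approximate Bayes factor (Wakefield), normalizes the Bayes factors into
posterior inclusion probabilities, and takes the smallest PIP-descending
prefix reaching the target coverage as the credible set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model import CredibleSet, CsMember

DEFAULT_PRIOR_VARIANCE = 0.04  # prior SD 0.2 on the allelic effect


def residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Project covariate columns (plus an intercept) out of each column of
    ``values`` by least squares.  Raises on rank-deficient covariates."""
    values = np.asarray(values, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != len(values):
        cov = cov.T
    # constant columns are harmlessly absorbed by the intercept
    keep = cov.std(axis=0) > 0 if cov.size else np.zeros(0, dtype=bool)
    C = np.column_stack([np.ones(len(values)), cov[:, keep]])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(C, values, rcond=None)
    return values - C @ coef


def map_cis_qtl(
    phenotypes: pd.DataFrame,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame,
    variant_table: pd.DataFrame,
    anchors: pd.DataFrame,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Covariate-adjusted linear scan of every variant-feature pair in cis.

    Parameters
    ----------
    phenotypes : individuals x features, standardized (zero mean, unit
        variance) per feature.
    dosages : individuals x variants, ALT allele counts; NaNs handled by
        per-test complete-case exclusion.
    variant_table : columns id, chrom, pos, maf.
    anchors : one row per feature with columns feature_id, chrom, anchor
        (TSS for genes, summit for peaks).
    window : maximum |variant pos - anchor| tested, in base pairs.

    Returns a frame (variant_id, feature_id, beta, se, p_nominal, maf); the
    effect is per ALT allele after projecting covariates out of both the
    phenotype and the dosage (Frisch-Waugh).
    """
    C = covariates.to_numpy(dtype=float)
    n, q = C.shape[0], C.shape[1] + 1  # + intercept
    pheno_raw = phenotypes.to_numpy(dtype=float)
    pheno_resid = residualize(pheno_raw, C)

    dos = dosages.to_numpy(dtype=float)
    has_nan = np.isnan(dos).any()
    if not has_nan:
        dos_resid = residualize(dos, C)

    var_pos = variant_table.set_index("id")["pos"]
    var_chrom = variant_table.set_index("id")["chrom"]
    var_maf = variant_table.set_index("id")["maf"]
    variant_ids = np.asarray(dosages.columns)
    pos_arr = var_pos.loc[variant_ids].to_numpy()
    chrom_arr = var_chrom.loc[variant_ids].to_numpy()

    out = []
    for frow in anchors.itertuples(index=False):
        fid, fchrom, anchor = frow.feature_id, frow.chrom, frow.anchor
        in_cis = (chrom_arr == fchrom) & (np.abs(pos_arr - anchor) <= window)
        if not in_cis.any():
            continue
        fcol = phenotypes.columns.get_loc(fid)
        y_full = pheno_resid[:, fcol]
        for k in np.flatnonzero(in_cis):
            vid = variant_ids[k]
            if has_nan:
                ok = ~np.isnan(dos[:, k])
                if ok.sum() < q + 2:
                    continue
                g = residualize(dos[ok, k : k + 1], C[ok])[:, 0]
                y = residualize(pheno_raw[ok, fcol : fcol + 1], C[ok])[:, 0]
                n_eff = int(ok.sum())
            else:
                g = dos_resid[:, k]
                y = y_full
                n_eff = n
            gg = g @ g
            if gg <= 1e-12:  # zero-variance dosage after residualization
                continue
            beta = (g @ y) / gg
            resid = y - beta * g
            dof = n_eff - q - 1
            sigma2 = (resid @ resid) / dof
            se = float(np.sqrt(sigma2 / gg))
            if se == 0.0:
                p = np.nextafter(0, 1)
            else:
                t = beta / se
                p = float(2.0 * stats.t.sf(abs(t), dof))
            out.append((vid, fid, float(beta), se, max(p, np.nextafter(0, 1)), float(var_maf.loc[vid])))
    return pd.DataFrame(out, columns=["variant_id", "feature_id", "beta", "se", "p_nominal", "maf"])


def wakefield_lbf(z: np.ndarray, v: np.ndarray, w: float = DEFAULT_PRIOR_VARIANCE) -> np.ndarray:
    """Approximate log Bayes factor from a z-score and its sampling variance
    V under a N(0, W) effect prior: lbf = 0.5 log(V/(V+W)) + z^2 W / (2(V+W)).
    """
    z = np.asarray(z, dtype=float)
    v = np.asarray(v, dtype=float)
    return 0.5 * np.log(v / (v + w)) + z**2 * w / (2.0 * (v + w))


def finemap_single_effect(
    records: pd.DataFrame,
    coverage: float = 0.95,
    prior_variance: float = DEFAULT_PRIOR_VARIANCE,
    cs_id: str = "cs",
    qtl_type: str = "eQTL",
    feature_id: str = "",
    region_id: str | None = None,
) -> tuple[CredibleSet, pd.DataFrame]:
    """Single-causal-variant fine-mapping of one region from summary stats.

    ``records`` needs columns variant_id, beta, se.  Returns the credible set
    and a per-variant frame (variant_id, lbf, pip) over the whole region.
    PIPs are the Bayes factors normalized over the region and sum to 1.
    """
    if len(records) < 2:
        raise ValueError("a fine-mapping region needs at least 2 variants")
    beta = records["beta"].to_numpy(dtype=float)
    se = records["se"].to_numpy(dtype=float)
    z = beta / se
    if np.allclose(z, 0.0):
        lbf = np.zeros(len(records))
        pip = np.full(len(records), 1.0 / len(records))
    else:
        lbf = wakefield_lbf(z, se**2, prior_variance)
        shifted = lbf - lbf.max()
        pip = np.exp(shifted) / np.exp(shifted).sum()

    order = np.argsort(-pip, kind="stable")
    cum = np.cumsum(pip[order])
    n_in = int(np.searchsorted(cum, coverage - 1e-12) + 1)
    n_in = min(n_in, len(records))
    chosen = order[:n_in]

    vids = records["variant_id"].to_numpy()
    members = [CsMember(str(vids[i]), float(pip[i]), float(lbf[i])) for i in chosen]
    cs = CredibleSet(
        cs_id=cs_id,
        qtl_type=qtl_type,
        feature_id=feature_id,
        members=members,
        coverage=coverage,
        region_id=region_id,
    )
    per_variant = pd.DataFrame({"variant_id": vids, "lbf": lbf, "pip": pip})
    return cs, per_variant
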