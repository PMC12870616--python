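"""End-to-end orchestration: simulate -> scan -> finemap -> annotate ->
collapse -> colocalize -> mediate -> integrate -> enrich.

Every stage writes its artifacts under the output directory and the run
closes with a manifest of file hashes, so a re-run with identical seeds is
checkably identical for the deterministic stages.  Per-stage structured
logging records the counts at every filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import coloc as cl
from . import enrichment as enr
from . import integrate as integ
from . import loci as lc
from . import mediation as med
from .io import write_credible_sets
from .model import CredibleSet
from .qtl import finemap_single_effect, map_cis_qtl
from .synthetic import Cohort, SimConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "scan",
    "finemap",
    "annotate",
    "collapse",
    "coloc",
    "mediate",
    "integrate",
    "gwas",
    "enrich",
)


@dataclass
class PipelineConfig:
    """Pipeline thresholds, at their usual defaults except where the toy
    scale warrants smaller minimums (region size, shared-variant count)."""

    cis_window: int = 1_000_000
    finemap_window_eqtl: int = 1_000_000
    finemap_window_caqtl: int = 250_000
    min_region_variants: int = 10
    lead_p_threshold: float = 1e-4
    coverage: float = 0.95
    prior_variance: float = 0.04
    cs_size_quantile: float = 0.75
    jaccard_threshold: float = 0.3
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    pp4_threshold: float = 0.5
    min_shared_variants: int = 5
    fdr_target: float = 0.05
    score_p_threshold: float = 0.05
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        for name in ("coverage", "pp4_threshold", "fdr_target", "score_p_threshold",
                     "coloc_p1", "coloc_p2", "coloc_p12", "cs_size_quantile",
                     "jaccard_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=0)


@dataclass
class PipelineResult:
    out_dir: Path
    cohort: Cohort
    summary: dict = field(default_factory=dict)
    eqtl_css: list[CredibleSet] = field(default_factory=list)
    caqtl_css: list[CredibleSet] = field(default_factory=list)
    coloc_results: list[cl.ColocResult] = field(default_factory=list)
    mediation: pd.DataFrame | None = None


def _finemap_qtl_type(
    scan: pd.DataFrame,
    qtl_type: str,
    anchors: pd.DataFrame,
    variant_table: pd.DataFrame,
    window: int,
    config: PipelineConfig,
) -> tuple[list[CredibleSet], dict[str, pd.Series]]:
    """Pick one lead per feature passing the scan threshold, build merged
    disjoint regions, and single-effect fine-map each feature inside its
    region.  Returns the credible sets and per-feature lbf vectors over the
    feature's whole region (indexed by variant id)."""
    best = scan.loc[scan.groupby("feature_id")["p_nominal"].idxmin()]
    best = best[best["p_nominal"] < config.lead_p_threshold]
    if best.empty:
        return [], {}
    vt = variant_table.set_index("id")
    leads = pd.DataFrame(
        {
            "id": best["variant_id"].to_numpy(),
            "chrom": vt.loc[best["variant_id"], "chrom"].to_numpy(),
            "pos": vt.loc[best["variant_id"], "pos"].to_numpy(),
            "feature_id": best["feature_id"].to_numpy(),
        }
    ).sort_values(["chrom", "pos"])
    regions = lc.merge_finemap_regions(
        leads[["id", "chrom", "pos"]],
        window=window,
        variant_table=variant_table,
        min_variants=config.min_region_variants,
    )
    region_of_lead = {
        lead: reg for reg in regions for lead in reg.lead_ids
    }
    css: list[CredibleSet] = []
    lbfs: dict[str, pd.Series] = {}
    for lead_row in leads.itertuples(index=False):
        reg = region_of_lead.get(lead_row.id)
        if reg is None:  # lead excluded (MHC or region too small)
            continue
        fid = lead_row.feature_id
        recs = scan[
            (scan["feature_id"] == fid)
            & (scan["variant_id"].isin(reg.variant_ids))
        ]
        if len(recs) < 2:
            continue
        cs, per_variant = finemap_single_effect(
            recs,
            coverage=config.coverage,
            prior_variance=config.prior_variance,
            cs_id=f"{qtl_type}_cs_{fid}",
            qtl_type=qtl_type,
            feature_id=fid,
            region_id=reg.region_id,
        )
        css.append(cs)
        lbfs[cs.cs_id] = per_variant.set_index("variant_id")["lbf"]
    logger.info("%s: %d features fine-mapped into credible sets", qtl_type, len(css))
    return css, lbfs


def run_pipeline(
    sim_config: SimConfig | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "pipeline_out",
    seed: int | None = None,
) -> PipelineResult:
    """Run the configured stages on a fresh synthetic cohort.

    Stage outputs land under ``out_dir``; a stage failure raises with the
    stage named, leaving earlier artifacts in place.  The manifest maps each
    written file to its sha256.
    """
    sim_config = sim_config or SimConfig()
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {"seed": seed if seed is not None else sim_config.seed}
    stages = set(config.stages)

    def stage_guard(name):
        class _Guard:
            def __enter__(self):
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
                logger.info("stage %s: done", name)
                return False

        return _Guard()

    # ------------------------------------------------------------- simulate
    with stage_guard("simulate"):
        cohort = simulate_cohort(sim_config, seed=seed)
        written += write_cohort(cohort, out / "cohort")
    result = PipelineResult(out_dir=out, cohort=cohort)

    gene_anchors = pd.DataFrame(
        {
            "feature_id": cohort.gene_table["id"],
            "chrom": cohort.gene_table["chrom"],
            "anchor": cohort.gene_table["tss"],
        }
    )
    peak_anchors = pd.DataFrame(
        {
            "feature_id": cohort.peak_table["id"],
            "chrom": cohort.peak_table["chrom"],
            "anchor": cohort.peak_table["summit"],
        }
    )
    anchor_map = dict(
        zip(gene_anchors["feature_id"], gene_anchors["anchor"])
    ) | dict(zip(peak_anchors["feature_id"], peak_anchors["anchor"]))

    if "scan" not in stages:
        return _finish(result, summary, written, config)

    # ----------------------------------------------------------------- scan
    with stage_guard("scan"):
        eqtl_scan = map_cis_qtl(
            _standardize(cohort.expression),
            cohort.dosages,
            cohort.covariates,
            cohort.variant_table,
            gene_anchors,
            window=config.cis_window,
        )
        caqtl_scan = map_cis_qtl(
            _standardize(cohort.accessibility),
            cohort.dosages,
            cohort.covariates,
            cohort.variant_table,
            peak_anchors,
            window=config.cis_window,
        )
        for name, df in (("eqtl_scan.tsv", eqtl_scan), ("caqtl_scan.tsv", caqtl_scan)):
            p = out / name
            df.to_csv(p, sep="\t", index=False)
            written.append(p)
        summary["n_eqtl_tests"] = int(len(eqtl_scan))
        summary["n_caqtl_tests"] = int(len(caqtl_scan))

    if "finemap" not in stages:
        return _finish(result, summary, written, config)

    # -------------------------------------------------------------- finemap
    with stage_guard("finemap"):
        eqtl_css, eqtl_lbfs = _finemap_qtl_type(
            eqtl_scan, "eQTL", gene_anchors, cohort.variant_table,
            config.finemap_window_eqtl, config,
        )
        caqtl_css, caqtl_lbfs = _finemap_qtl_type(
            caqtl_scan, "caQTL", peak_anchors, cohort.variant_table,
            config.finemap_window_caqtl, config,
        )
        result.eqtl_css, result.caqtl_css = eqtl_css, caqtl_css
        write_credible_sets(eqtl_css, out / "eqtl_credible_sets")
        write_credible_sets(caqtl_css, out / "caqtl_credible_sets")
        written += [
            out / "eqtl_credible_sets.tsv", out / "eqtl_credible_sets.json",
            out / "caqtl_credible_sets.tsv", out / "caqtl_credible_sets.json",
        ]
        summary["n_eqtl_cs"] = len(eqtl_css)
        summary["n_caqtl_cs"] = len(caqtl_css)

    all_css = eqtl_css + caqtl_css

    # ------------------------------------------------------------- annotate
    if "annotate" in stages and all_css:
        with stage_guard("annotate"):
            annotation = ann.annotate_credible_sets(
                all_css,
                cohort.variant_table,
                cohort.peak_table.rename(columns={"summit": "anchor"}),
                cohort.gene_model,
                cohort.segmentation,
                anchor_map,
            )
            p = out / "cs_annotation.tsv"
            annotation.to_csv(p, sep="\t", index=False)
            written.append(p)
            summary["caqtl_category_counts"] = (
                annotation[annotation["qtl_type"] == "caQTL"]["category"]
                .value_counts()
                .to_dict()
            )

    # ------------------------------------------------------------- collapse
    if "collapse" in stages and all_css:
        with stage_guard("collapse"):
            filtered = ann.filter_cs_size_quantile(all_css, config.cs_size_quantile)
            logger.info("size filter: %d of %d CSs retained", len(filtered), len(all_css))
            locus_rows = []
            for qtl_type in ("eQTL", "caQTL"):
                subset = [cs for cs in filtered if cs.qtl_type == qtl_type]
                if not subset:
                    continue
                loci = lc.build_loci(
                    subset, cohort.variant_table, threshold=config.jaccard_threshold
                )
                mult = lc.locus_target_multiplicity(
                    loci, {cs.cs_id: cs.feature_id for cs in subset}
                )
                mult.insert(0, "qtl_type", qtl_type)
                locus_rows.append(mult)
                summary[f"n_{qtl_type}_loci"] = len(loci)
                summary[f"{qtl_type}_single_target_frac"] = float(
                    (mult["target_count"] == 1).mean()
                )
            if locus_rows:
                p = out / "loci.tsv"
                pd.concat(locus_rows).to_csv(p, sep="\t", index=False)
                written.append(p)

    # ---------------------------------------------------------------- coloc
    shared_pairs: list[tuple[str, str]] = []
    if "coloc" in stages and eqtl_css and caqtl_css:
        with stage_guard("coloc"):
            priors = cl.ColocPriors(config.coloc_p1, config.coloc_p2, config.coloc_p12)
            rows = []
            for e_cs in eqtl_css:
                e_lbf = eqtl_lbfs[e_cs.cs_id]
                for c_cs in caqtl_css:
                    c_lbf = caqtl_lbfs[c_cs.cs_id]
                    shared_idx = e_lbf.index.intersection(c_lbf.index)
                    if len(shared_idx) < config.min_shared_variants:
                        continue
                    res = cl.coloc_from_lbf(
                        e_lbf.loc[shared_idx],
                        c_lbf.loc[shared_idx],
                        priors=priors,
                        min_shared=config.min_shared_variants,
                        cs1=e_cs.cs_id,
                        cs2=c_cs.cs_id,
                    )
                    if res is None:
                        continue
                    rows.append(
                        {
                            "cs1": res.cs1, "cs2": res.cs2,
                            "pp_h0": res.pp_h0, "pp_h1": res.pp_h1,
                            "pp_h2": res.pp_h2, "pp_h3": res.pp_h3,
                            "pp_h4": res.pp_h4,
                            "shared": res.pp_h4 > config.pp4_threshold,
                        }
                    )
                    result.coloc_results.append(res)
            coloc_table = pd.DataFrame(rows)
            p = out / "coloc.tsv"
            coloc_table.to_csv(p, sep="\t", index=False)
            written.append(p)
            if len(coloc_table):
                shared_pairs = [
                    (r.cs1, r.cs2)
                    for r in coloc_table[coloc_table["shared"]].itertuples(index=False)
                ]
            summary["n_coloc_tested"] = int(len(coloc_table))
            summary["n_coloc_shared"] = len(shared_pairs)

    # -------------------------------------------------------------- mediate
    if "mediate" in stages and shared_pairs:
        with stage_guard("mediate"):
            eqtl_by_id = {cs.cs_id: cs for cs in eqtl_css}
            caqtl_by_id = {cs.cs_id: cs for cs in caqtl_css}
            locus_of = cl.collapse_coloc_loci(shared_pairs)
            trip_rows = [
                {
                    "locus_id": locus_of[(e_id, c_id)],
                    "gene": eqtl_by_id[e_id].feature_id,
                    "peak": caqtl_by_id[c_id].feature_id,
                    "exposure_chrom_to_gene": caqtl_by_id[c_id].lead_variant,
                    "exposure_gene_to_chrom": eqtl_by_id[e_id].lead_variant,
                }
                for e_id, c_id in shared_pairs
            ]
            triplets = pd.DataFrame(trip_rows)
            if len(triplets) >= 50:
                mediation = med.run_bidirectional(
                    triplets,
                    cohort.expression,
                    cohort.accessibility,
                    cohort.dosages,
                    cohort.covariates,
                    fdr_target=config.fdr_target,
                )
                result.mediation = mediation
                p = out / "mediation.tsv"
                mediation.to_csv(p, sep="\t", index=False)
                written.append(p)
                summary["mediation"] = med.summarize_directions(mediation)
            else:
                logger.warning(
                    "mediation skipped: %d triplets < 50 needed for the "
                    "posterior mixture fit", len(triplets),
                )
                summary["mediation"] = {"skipped": True, "n_triplets": len(triplets)}

    # ------------------------------------------------------------ integrate
    sig_scores = set(
        cohort.variant_scores[
            cohort.variant_scores["p_empirical"] < config.score_p_threshold
        ]["variant_id"]
    )
    if "integrate" in stages and all_css:
        with stage_guard("integrate"):
            groups = integ.membership_groups(
                eqtl_css, caqtl_css, shared_pairs, sig_scores
            )
            p = out / "membership_groups.tsv"
            groups.to_csv(p, sep="\t", index=False)
            written.append(p)
            summary["membership_group_counts"] = (
                groups["group"].value_counts().to_dict()
            )

            # concordance of predicted vs empirical allelic effects
            caqtl_best = (
                caqtl_scan.loc[caqtl_scan.groupby("variant_id")["p_nominal"].idxmin()]
                [["variant_id", "feature_id", "beta", "p_nominal"]]
            )
            categories = _variant_categories(cohort, caqtl_best)
            caqtl_sig = {
                v for cs in caqtl_css for v in cs.variant_ids
            }
            concordance = integ.effect_concordance(
                cohort.variant_scores[["variant_id", "log_afc"]],
                caqtl_best,
                categories,
                sig_scores,
                caqtl_sig,
            )
            summary["effect_concordance"] = concordance

            if "coverage" in cohort.peak_table.columns:
                cov = _variant_peak_coverage(cohort)
                in_cs = {v for cs in all_css for v in cs.variant_ids}
                spec_cov = [c for v, c in cov.items() if v in sig_scores and v not in in_cs]
                shared_cov = [c for v, c in cov.items() if v in sig_scores and v in in_cs]
                if len(spec_cov) >= 2 and len(shared_cov) >= 2:
                    cmp = integ.coverage_compare(np.array(spec_cov), np.array(shared_cov))
                    summary["coverage_compare"] = asdict(cmp)

    # ----------------------------------------------------------------- gwas
    if "gwas" in stages and all_css:
        with stage_guard("gwas"):
            gwas_summary, perm = _gwas_stage(
                cohort, eqtl_css, caqtl_css, eqtl_lbfs, caqtl_lbfs,
                sig_scores, config, out, written, seed,
            )
            summary["gwas"] = gwas_summary
            if perm is not None:
                summary["gwas_permutation"] = perm

    # --------------------------------------------------------------- enrich
    if "enrich" in stages and "caqtl_category_counts" in summary:
        with stage_guard("enrich"):
            summary["enrichment_examples"] = _enrich_stage(annotation)

    return _finish(result, summary, written, config)


def _variant_categories(cohort: Cohort, caqtl_best: pd.DataFrame) -> dict[str, str]:
    """Variant-level C1/C2/C3 for every scored variant relative to its best
    caQTL peak."""
    best_peak = dict(zip(caqtl_best["variant_id"], caqtl_best["feature_id"]))
    out: dict[str, str] = {}
    vt = cohort.variant_table.set_index("id")
    for vid in cohort.variant_scores["variant_id"]:
        if vid not in vt.index:
            continue
        pos, chrom = int(vt.loc[vid, "pos"]), vt.loc[vid, "chrom"]
        peaks = cohort.peak_table[cohort.peak_table["chrom"] == chrom]
        containing = peaks[(peaks["start"] <= pos) & (pos < peaks["end"])]["id"]
        if containing.empty:
            out[vid] = "C3"
        elif best_peak.get(vid) in set(containing):
            out[vid] = "C1"
        else:
            out[vid] = "C2"
    return out


def _variant_peak_coverage(cohort: Cohort) -> dict[str, float]:
    cov = {}
    vt = cohort.variant_table.set_index("id")
    scored = cohort.variant_scores["variant_id"]
    for vid in scored:
        pos, chrom = int(vt.loc[vid, "pos"]), vt.loc[vid, "chrom"]
        peaks = cohort.peak_table[
            (cohort.peak_table["chrom"] == chrom)
            & (cohort.peak_table["start"] <= pos)
            & (pos < cohort.peak_table["end"])
        ]
        if len(peaks):
            cov[vid] = float(peaks["coverage"].iloc[0])
    return cov


def _gwas_stage(
    cohort, eqtl_css, caqtl_css, eqtl_lbfs, caqtl_lbfs,
    sig_scores, config, out, written, seed,
):
    """Colocalize GWAS credible sets against molQTL signals, summarize per
    trait, and run the score-hit permutation enrichment over molQTL CSs by
    GWAS-colocalization class."""
    priors = cl.ColocPriors(config.coloc_p1, config.coloc_p2, config.coloc_p12)
    gwas = cohort.gwas_credsets
    call_rows = []
    for cs_id, grp in gwas.groupby("cs_id"):
        g_lbf = grp.set_index("variant_id")["lbf"]
        g_lbf = g_lbf[~g_lbf.index.duplicated()]
        for qtl_type, lbfs in (("eQTL", eqtl_lbfs), ("caQTL", caqtl_lbfs)):
            for mol_id, m_lbf in lbfs.items():
                shared_idx = g_lbf.index.intersection(m_lbf.index)
                if len(shared_idx) < 2:
                    continue
                res = cl.coloc_from_lbf(
                    g_lbf.loc[shared_idx], m_lbf.loc[shared_idx],
                    priors=priors, cs1=str(cs_id), cs2=mol_id,
                )
                call_rows.append(
                    {
                        "cs_id": cs_id, "molqtl_cs": mol_id, "qtl_type": qtl_type,
                        "pp_h4": res.pp_h4,
                        "shared": res.pp_h4 > config.pp4_threshold,
                    }
                )
    calls = pd.DataFrame(
        call_rows, columns=["cs_id", "molqtl_cs", "qtl_type", "pp_h4", "shared"]
    )
    p = out / "gwas_coloc.tsv"
    calls.to_csv(p, sep="\t", index=False)
    written.append(p)

    cs_variant_sets = {
        cs.cs_id: set(cs.variant_ids) for cs in eqtl_css + caqtl_css
    }
    hit_rows = []
    for cs_id, grp in gwas.groupby("cs_id"):
        members = set(grp["variant_id"])
        hits = members & sig_scores
        in_qtl = any(hits & vs for vs in cs_variant_sets.values())
        hit_rows.append(
            {"cs_id": cs_id, "has_score_hit": bool(hits), "hit_in_qtl_cs": in_qtl}
        )
    gwas_table = gwas[["trait", "cs_id"]].drop_duplicates()
    summary_df = cl.gwas_coloc_summary(gwas_table, calls, pd.DataFrame(hit_rows))
    p = out / "gwas_summary.tsv"
    summary_df.to_csv(p, sep="\t", index=False)
    written.append(p)
    gwas_summary = {
        "median_frac_colocalized": float(summary_df["frac_colocalized"].median()),
        "median_frac_caqtl_only": float(summary_df["frac_caQTL_only"].median()),
        "median_frac_score_hit": float(summary_df["frac_score_hit"].median()),
    }

    # permutation enrichment of score hits in GWAS-colocalized molQTL CSs
    perm_summary = None
    if len(calls):
        shared_mol = set(calls[calls["shared"]]["molqtl_cs"])
        h, m, chroms, labels, bg = [], [], [], [], []
        vt = cohort.variant_table.set_index("id")
        scored = set(cohort.variant_scores["variant_id"])
        for cs in eqtl_css + caqtl_css:
            callable_v = [v for v in cs.variant_ids if v in scored]
            if not callable_v:
                continue
            h.append(sum(v in sig_scores for v in callable_v))
            m.append(len(callable_v))
            chroms.append(vt.loc[callable_v[0], "chrom"])
            is_bg = cs.cs_id not in shared_mol
            labels.append("background" if is_bg else "gwas_colocalized")
            bg.append(is_bg)
        if len(h) >= 4 and any(bg) and not all(bg):
            perm = enr.permutation_enrichment(
                np.array(h), np.array(m), np.array(chroms), np.array(labels),
                np.array(bg), n_perm=10_000,
                seed=(seed or 0) + 17,
            )
            perm_summary = {
                k: {"observed": v.observed, "p": v.p_one_sided, "report": v.report_p()}
                for k, v in perm.items()
            }
    return gwas_summary, perm_summary


def _enrich_stage(annotation: pd.DataFrame) -> dict:
    """Representative enrichment calls on the annotated CS table."""
    out = {}
    ca = annotation[annotation["qtl_type"] == "caQTL"]
    if len(ca) >= 4:
        c1 = ca["category"] == "in_caPeak"
        promoter = ca["state_label"] == "Promoter"
        a = int((c1 & promoter).sum())
        b = int((c1 & ~promoter).sum())
        c = int((~c1 & promoter).sum())
        d = int((~c1 & ~promoter).sum())
        try:
            res = enr.fisher_2x2(a, b, c, d, comparison="C1_promoter_vs_rest")
            out["c1_promoter_fisher"] = {
                "odds_ratio": res.odds_ratio, "p": res.p,
                "ci": [res.ci_low, res.ci_high],
            }
        except ValueError:
            pass
    counts = annotation.groupby(["qtl_type", "region_label"]).size().unstack(fill_value=0)
    if counts.shape == (2, counts.shape[1]) and counts.shape[1] >= 2:
        keep = counts.loc[:, (counts > 0).all(axis=0)]
        if keep.shape[1] >= 2:
            chi2, p = enr.proportion_chisq(keep.to_numpy())
            out["region_composition_chisq"] = {"chi2": chi2, "p": p}
    return out


def _finish(result, summary, written, config):
    out = result.out_dir
    manifest = {
        "config": asdict(config),
        "sim_config": asdict(result.cohort.config),
        "files": {str(p.relative_to(out)): _sha256(p) for p in written if p.exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True, default=str))
    result.summary = summary
    return result
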