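"""Readers and writers for the plain-text tables the pipeline exchanges.

Formats: BED3/4/6 (0-based half-open), a minimal biallelic VCF with GT
genotypes, TSVs with mandatory headers, and credible-set tables stored as one
row per (cs_id, variant) pair plus a JSON sidecar of CS-level metadata.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CredibleSet, CsMember

logger = logging.getLogger(__name__)

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3/4/6 file into a frame with half-open coordinates.

    Records with start >= end are rejected (dropped) with a logged line
    number; lines that cannot be parsed at all raise, naming the line.
    """
    rows = []
    keep_cols = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                logger.warning("%s: line %d: start >= end, record rejected", path, lineno)
                continue
            keep_cols = max(keep_cols, min(len(parts), 6))
            rows.append([parts[0], start, end] + parts[3:6])
    cols = BED_COLUMNS[:keep_cols] if keep_cols else BED_COLUMNS[:3]
    df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(records: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in records.columns]
    records[cols].to_csv(path, sep="\t", header=False, index=False)


def read_vcf_lite(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a minimal VCF into (variant table, dosage matrix).

    Dosage = ALT allele count per GT call; ``./.`` becomes NaN (complete-case
    exclusion happens per test downstream).  Multi-allelic records are
    rejected.  Positions come back 0-based.
    """
    samples: list[str] = []
    var_rows = []
    dosage_rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            if "," in alt:
                raise ValueError(f"{path}: line {lineno}: multi-allelic record {vid}")
            gt_index = parts[8].split(":").index("GT")
            dosages = []
            for cell in parts[9:]:
                gt = cell.split(":")[gt_index]
                alleles = gt.replace("|", "/").split("/")
                if "." in alleles:
                    dosages.append(np.nan)
                else:
                    dosages.append(float(sum(int(x) for x in alleles)))
            var_rows.append((vid, chrom, pos - 1, ref, alt))
            dosage_rows.append(dosages)
    variants = pd.DataFrame(var_rows, columns=["id", "chrom", "pos", "ref", "alt"])
    dosage = pd.DataFrame(
        np.asarray(dosage_rows, dtype=float).T if dosage_rows else np.empty((len(samples), 0)),
        index=samples,
        columns=variants["id"].tolist(),
    )
    return variants, dosage


def write_vcf_lite(
    variants: pd.DataFrame, dosage: pd.DataFrame, path: str | Path
) -> None:
    """Write a minimal VCF (GT only) from a variant table and dosage matrix.

    Dosage 1 is written as the unphased het ``0/1``; positions are converted
    to 1-based.
    """
    samples = list(dosage.index)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        mat = dosage.to_numpy()
        for k, row in enumerate(variants.itertuples(index=False)):
            gts = [gt_map.get(v, "./.") for v in mat[:, k]]
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_credible_sets(css: list[CredibleSet], prefix: str | Path) -> None:
    """Write CSs as <prefix>.tsv (one row per cs_id, variant) plus
    <prefix>.json with CS-level metadata."""
    prefix = Path(prefix)
    rows = [
        (cs.cs_id, m.variant_id, m.pip, m.lbf)
        for cs in css
        for m in cs.members
    ]
    pd.DataFrame(rows, columns=["cs_id", "variant_id", "pip", "lbf"]).to_csv(
        prefix.with_suffix(".tsv"), sep="\t", index=False
    )
    meta = {
        cs.cs_id: {
            "qtl_type": cs.qtl_type,
            "feature_id": cs.feature_id,
            "coverage": cs.coverage,
            "region_id": cs.region_id,
        }
        for cs in css
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_credible_sets(prefix: str | Path) -> list[CredibleSet]:
    prefix = Path(prefix)
    table = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    css = []
    for cs_id, grp in table.groupby("cs_id", sort=False):
        m = meta[str(cs_id)]
        css.append(
            CredibleSet(
                cs_id=str(cs_id),
                qtl_type=m["qtl_type"],
                feature_id=m["feature_id"],
                members=[
                    CsMember(r.variant_id, r.pip, r.lbf)
                    for r in grp.itertuples(index=False)
                ],
                coverage=m["coverage"],
                region_id=m.get("region_id"),
            )
        )
    return css
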