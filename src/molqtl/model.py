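"""Shared data model for the molQTL integration pipeline.

Coordinates are 0-based half-open everywhere in memory; 1-based coordinates
appear only in VCF-style output.  A credible set (CS) is the unit of a
fine-mapped association signal: its member variants carry posterior inclusion
probabilities (PIPs) and per-variant log Bayes factors (lbf) contrasting
association against no association for one molecular trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Variant:
    """A biallelic variant with its minor allele frequency."""

    id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    maf: float

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"MAF of {self.id} must be in (0, 0.5], got {self.maf}")
        if self.pos < 0:
            raise ValueError(f"negative position for {self.id}")


@dataclass(frozen=True)
class AssociationRecord:
    """One variant-feature association test (allelic effect, ALT vs REF)."""

    variant_id: str
    feature_id: str
    beta: float
    se: float
    p_nominal: float
    maf: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if not (0.0 < self.p_nominal <= 1.0):
            raise ValueError("nominal p must be in (0, 1]")


@dataclass(frozen=True)
class CsMember:
    variant_id: str
    pip: float
    lbf: float


@dataclass
class CredibleSet:
    """A fine-mapped signal: member variants with PIPs and log Bayes factors.

    ``qtl_type`` is "eQTL" or "caQTL"; ``feature_id`` names the regulated
    eGene or caPeak; ``coverage`` is the target posterior coverage of the set.
    """

    cs_id: str
    qtl_type: str
    feature_id: str
    members: list[CsMember]
    coverage: float = 0.95
    region_id: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"credible set {self.cs_id} has no members")
        for m in self.members:
            if not (0.0 <= m.pip <= 1.0):
                raise ValueError(f"PIP out of [0,1] in {self.cs_id}")
        if sum(m.pip for m in self.members) > 1.0 + 1e-6 * len(self.members):
            raise ValueError(f"member PIPs of {self.cs_id} exceed 1")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def variant_ids(self) -> list[str]:
        return [m.variant_id for m in self.members]

    @property
    def lead_variant(self) -> str:
        """Member with the highest PIP (mediation exposure)."""
        return max(self.members, key=lambda m: m.pip).variant_id


@dataclass(frozen=True)
class Feature:
    """A regulated molecular feature: a gene (anchored at its TSS) or an
    accessibility peak (anchored at its summit).

    ``annotation`` classifies peaks as ``promoter`` (overlapping a TSS) or
    ``cis-CRE`` (not); it is None for genes.
    """

    id: str
    kind: str  # "gene" | "peak"
    interval: GenomicInterval
    anchor: int
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "peak"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "peak":
            if not self.interval.contains(self.anchor):
                raise ValueError(f"summit of {self.id} outside its interval")
            if self.annotation not in ("promoter", "cis-CRE"):
                raise ValueError(f"peak {self.id} needs a promoter/cis-CRE annotation")


@dataclass(frozen=True)
class VariantScore:
    """Sequence-model allelic prediction for one variant.

    ``log_afc`` is the predicted allelic log fold-change (ALT/REF) on local
    chromatin accessibility; ``p_empirical`` its empirical significance.
    """

    variant_id: str
    log_afc: float
    p_empirical: float

    @property
    def significant(self) -> bool:
        return self.p_empirical < 0.05


@dataclass
class FinemapRegion:
    """A disjoint fine-mapping region built around one or more lead variants."""

    region_id: str
    chrom: str
    start: int
    end: int
    variant_ids: list[str] = field(default_factory=list)
    lead_ids: list[str] = field(default_factory=list)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class Locus:
    """A connected component of the CS interval-Jaccard overlap graph."""

    locus_id: str
    cs_ids: list[str]
    interval: GenomicInterval
    target_count: int = 0
    target_bin: str = ""
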