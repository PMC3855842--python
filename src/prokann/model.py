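"""Core value types shared across the annotation pipeline.

All genomic coordinates in this package are 1-based and inclusive at both
ends (the native convention of GFF3 and NCBI feature tables).  Converters
in :mod:`prokann.formats_io` own every off-by-one adjustment; nothing
downstream ever shifts a coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

FEATURE_TYPES = ("CDS", "rRNA", "tRNA")
RNA_TYPES = ("rRNA", "tRNA")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a contig, 1-based inclusive."""

    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValueError("contig_id must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if on different contigs)."""
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass(frozen=True)
class GeneCall:
    """One called feature (CDS, rRNA or tRNA) from one source.

    ``source`` names the predictor that emitted the call (or ``"consensus"``
    after merging).  ``partial`` flags genes truncated at a contig edge,
    which are exempt from minimum-length filtering.
    """

    gene_id: str
    interval: GenomicInterval
    feature_type: str
    source: str
    rna_subtype: str | None = None
    score: float | None = None
    partial: bool = False

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")

    # convenience pass-throughs used all over the pipeline
    @property
    def contig_id(self) -> str:
        return self.interval.contig_id

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return self.interval.length

    def with_id(self, gene_id: str) -> "GeneCall":
        return replace(self, gene_id=gene_id)


@dataclass(frozen=True)
class HomologyHit:
    """One ranked similarity-search hit of a gene against one database."""

    query_id: str
    db: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    subject_desc: str = ""
    species: str | None = None
    query_cov: float | None = None

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def hit_rank_key(hit: HomologyHit) -> tuple:
    """Total order on hits for one query: bitscore desc, e-value asc, subject asc."""
    return (-hit.bitscore, hit.evalue, hit.subject_id)


@dataclass(frozen=True)
class DomainHit:
    """One protein-signature (domain) hit, optionally InterPro-integrated."""

    query_id: str
    analysis: str
    signature_acc: str
    signature_desc: str = ""
    ipr_acc: str | None = None
    go_terms: tuple[str, ...] = ()
    evalue: float | None = None


@dataclass(frozen=True)
class ProductAssignment:
    """The chosen product name for one gene plus its evidence source."""

    gene_id: str
    product: str
    source: str  # database label, "domain", or "none"
    status: str  # "functional" or "hypothetical"

    def __post_init__(self) -> None:
        if self.status not in ("functional", "hypothetical"):
            raise ValueError(f"bad status {self.status!r}")


@dataclass
class HierarchyNode:
    """Node of a rooted multi-level summary tree with a distinct-gene count."""

    name: str
    count: int = 0
    children: list["HierarchyNode"] = field(default_factory=list)

    def child(self, name: str) -> "HierarchyNode | None":
        for c in self.children:
            if c.name == name:
                return c
        return None
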