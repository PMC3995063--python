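"""Core record types shared across the pipeline.

Coordinates are 0-based throughout; a cleavage site at position ``p`` is the
last transcribed nucleotide and occupies the half-open interval ``[p, p+1)``
in BED output.  ``strand`` always refers to the strand of the *transcript*
whose 3' end a record marks: direct RNA-sequencing reads are sequenced from
the polyA tail and are reverse-complementary to the RNA, so the 5' mapped end
of a read is the transcript's cleavage position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class MappedReadEnd:
    """One read's inferred cleavage position plus the QC metadata needed to
    filter it (uniqueness, mapped length, aligner score)."""

    chrom: str
    cleavage_pos: int
    strand: str
    sample_id: str
    read_length: int
    map_score: float
    unique: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


@dataclass(frozen=True)
class QcThresholds:
    """Read-level QC cutoffs.

    Defaults: uniquely mapped reads of >=21 nt with an alignment score >=4
    are kept; a read is discarded as an internal-priming artifact when the
    first six or more of the ten genomic nucleotides immediately 3' of its
    cleavage position (on the transcript strand) are adenines.
    """

    min_length: int = 21
    min_score: float = 4.0
    priming_window: int = 10
    priming_min_leading_a: int = 6

    def __post_init__(self) -> None:
        if min(self.min_length, self.priming_window, self.priming_min_leading_a) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class CleavageCluster:
    """A maximal single-linkage group of read ends on one (chrom, strand).

    ``members`` maps each distinct cleavage position to per-sample read
    counts; adjacent member positions are < gap nucleotides apart.
    """

    chrom: str
    strand: str
    members: dict[int, dict[str, int]]  # position -> {sample_id: count}

    @property
    def span(self) -> tuple[int, int]:
        positions = sorted(self.members)
        return positions[0], positions[-1]

    @property
    def total_reads(self) -> int:
        return sum(c for counts in self.members.values() for c in counts.values())


@dataclass
class PolyASite:
    """A called polyA site: the representative (read-weighted median) position
    of a cleavage cluster with per-sample read counts."""

    chrom: str
    strand: str
    position: int
    counts: dict[str, int]
    site_id: str = ""

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def samples_with_reads(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)


CATEGORIES = ("5UTR", "CODING", "3UTR", "ncGENE", "PROMOTER", "DOWNSTREAM", "INTERGENIC")


@dataclass
class AnnotatedSite:
    """A polyA site with its genomic category and, where applicable, the gene
    it is attributed to for the APA analysis.

    DOWNSTREAM sites carry the upstream gene whose 3' end lies within 1 kb;
    PROMOTER and INTERGENIC sites carry no gene and are excluded from APA
    testing.
    """

    site: PolyASite
    category: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[tuple[int, int]]  # half-open genomic intervals, sorted
    cds: Optional[tuple[int, int]] = None  # genomic span of the CDS

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModel:
    """Gene with transcript structures; 5'/3' UTR intervals are derived from
    exon/CDS geometry when the annotation does not provide UTR features."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"

    def three_prime_end(self) -> int:
        """Genomic coordinate of the most 3' base of the gene span."""
        return self.end - 1 if self.strand == "+" else self.start

    def utr3_intervals(self) -> list[tuple[int, int]]:
        """Exonic pieces 3' of the CDS over all transcripts (genomic, half-open)."""
        out: list[tuple[int, int]] = []
        for tx in self.transcripts:
            if tx.cds is None:
                continue
            cs, ce = tx.cds
            for es, ee in tx.exons:
                if self.strand == "+":
                    lo, hi = max(es, ce), ee
                else:
                    lo, hi = es, min(ee, cs)
                if lo < hi:
                    out.append((lo, hi))
        return out

    def utr5_intervals(self) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for tx in self.transcripts:
            if tx.cds is None:
                continue
            cs, ce = tx.cds
            for es, ee in tx.exons:
                if self.strand == "+":
                    lo, hi = es, min(ee, cs)
                else:
                    lo, hi = max(es, ce), ee
                if lo < hi:
                    out.append((lo, hi))
        return out


@dataclass
class GeneSiteTable:
    """Per-gene samples x polyA-sites read-count contingency table.

    ``site_positions`` are ordered 5'->3' in transcript orientation (proximal
    first); ``counts`` holds one row per sample over the *included* sites
    (those passing the 10%-of-gene-reads rule in at least one sample).
    Reads at excluded minor sites are dropped, not pooled.
    """

    gene_id: str
    strand: str
    site_positions: list[int]
    counts: dict[str, list[int]]  # sample_id -> counts aligned with site_positions
    excluded_positions: list[int] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    @property
    def testable(self) -> bool:
        return self.n_sites >= 2

    def row(self, sample_id: str) -> list[int]:
        return self.counts[sample_id]


@dataclass
class APAVerdict:
    """Per-gene outcome of the pairwise Fisher tests and the group-consistency
    rule: significant iff every tumor-tumor q-value exceeds the FDR threshold
    (the tumor group is homogeneous) and every tumor-vs-reference q-value is
    below it."""

    gene_id: str
    p_values: dict[tuple[str, str], float]
    q_values: dict[tuple[str, str], float]
    significant: bool
    testable: bool = True


@dataclass
class CurationDecision:
    """Outcome of the five post-hoc selection rules for one significant gene.

    ``rule_fired`` is the first rule (in order 1->5) that removes the gene:
    tandem_transcript, overlapping_gene, low_read_support,
    distal_dominant_tumor, proximal_dominant_reference — or "none".
    """

    gene_id: str
    rule_fired: str
    kept: bool
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MirnaTargetSite:
    mirna_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("target interval must be non-empty")


@dataclass
class LossReport:
    """miRNA target sites lost when the 3'UTR is truncated from the distal to
    the proximal cleavage position; ``lost_expressed`` restricts to miRNAs in
    the supplied expressed set."""

    gene_id: str
    region: tuple[int, int]  # genomic half-open interval of the truncated region
    lost: list[MirnaTargetSite]
    lost_expressed: list[MirnaTargetSite]


@dataclass
class QpcrRecord:
    sample_id: str
    gene_id: str
    amplicon: str  # "proximal" or "distal"
    ct_values: list[float]


@dataclass
class IsoformRatio:
    sample_id: str
    gene_id: str
    ratio: float
    normalized_ratio: Optional[float] = None
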