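"""Read-level quality control for mapped 3'-end reads.

Three filters are applied, mirroring standard DRS 3'-end processing:

1. leading-T trimming (raw sequence space; Ts at the read start arise from
   inefficient locking of the RNA against the polyT primer),
2. mapping filters (uniquely mapped, length >= 21 nt, score >= 4),
3. internal-priming removal: a read whose genomic context immediately 3' of
   the cleavage position starts with six or more adenines (within a 10-nt
   window, on the transcript strand) is discarded as an oligo-dT
   mispriming artifact rather than a true polyA site.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .model import MappedReadEnd, QcThresholds

_NUCLEOTIDES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def trim_leading_t(read_sequence: str) -> str:
    """Strip the maximal run of leading Ts from a raw read sequence.

    An empty result means the read was all Ts and is unusable.
    Raises ``ValueError`` on non-nucleotide characters.
    """
    seq = read_sequence.upper()
    if not _NUCLEOTIDES.issuperset(seq):
        bad = sorted(set(seq) - _NUCLEOTIDES)
        raise ValueError(f"non-nucleotide characters in read: {bad}")
    return seq.lstrip("T")


def passes_mapping_filters(read: MappedReadEnd, thresholds: QcThresholds | None = None) -> bool:
    """True iff the read is uniquely mapped with length and score at or above
    the minima (boundaries inclusive)."""
    t = thresholds or QcThresholds()
    return bool(read.unique) and read.read_length >= t.min_length and read.map_score >= t.min_score


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    """Clipped genomic slice; bases beyond the chromosome ends are simply
    absent (callers treat missing bases as non-A)."""
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    seq = genome[chrom]
    return str(seq[max(start, 0):max(end, 0)])


def priming_context(read: MappedReadEnd, genome: Mapping[str, str],
                    thresholds: QcThresholds | None = None) -> str:
    """The genomic nucleotides immediately 3' of the cleavage position, read
    on the transcript strand (for '-' strand reads: reverse complement of the
    window immediately 5' in reference orientation)."""
    t = thresholds or QcThresholds()
    w = t.priming_window
    p = read.cleavage_pos
    if read.strand == "+":
        return _fetch(genome, read.chrom, p + 1, p + 1 + w).upper()
    return reverse_complement(_fetch(genome, read.chrom, p - w, p).upper())


def _leading_a_run(context: str) -> int:
    n = 0
    for base in context:
        if base != "A":
            break
        n += 1
    return n


def is_internal_priming(read: MappedReadEnd, genome: Mapping[str, str],
                        thresholds: QcThresholds | None = None) -> bool:
    """True iff the downstream genomic context begins with a run of >= 6
    adenines — evidence the read was primed on genomic A's, not a polyA tail.

    The criterion is a *leading* run: "AAAAAGAAAA" (run of 5) does not fire
    even though 9 of 10 bases are A. Windows truncated by a chromosome end
    count missing bases as non-A (conservative retention).
    """
    t = thresholds or QcThresholds()
    return _leading_a_run(priming_context(read, genome, t)) >= t.priming_min_leading_a


def filter_reads(reads: Iterable[MappedReadEnd], genome: Mapping[str, str],
                 thresholds: QcThresholds | None = None) -> tuple[list[MappedReadEnd], dict[str, int]]:
    """Apply mapping filters then internal-priming removal.

    Returns the retained reads and a tally with keys ``input``,
    ``failed_mapping``, ``internal_priming`` and ``kept``.  Per-read decisions
    are independent, so the filter is idempotent and order-independent.
    """
    t = thresholds or QcThresholds()
    kept: list[MappedReadEnd] = []
    stats = {"input": 0, "failed_mapping": 0, "internal_priming": 0, "kept": 0}
    for read in reads:
        stats["input"] += 1
        if not passes_mapping_filters(read, t):
            stats["failed_mapping"] += 1
            continue
        if is_internal_priming(read, genome, t):
            stats["internal_priming"] += 1
            continue
        kept.append(read)
    stats["kept"] = len(kept)
    return kept, stats
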