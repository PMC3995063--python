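"""Programmatic post-hoc selection of genuine tumor-specific 3'-truncation.

Significant genes pass through five ordered removal rules; the first rule
that fires is recorded and a gene is kept only when none fires:

1. tandem_transcript — the differentially used ("implicated") sites do not
   all lie within the gene's own transcripts (plus its <=1 kb downstream
   flank): the signal only distinguishes a longer read-through/tandem
   transcript containing the gene.
2. overlapping_gene — an implicated site also lies within a different
   same-strand gene whose expression could generate it.
3. low_read_support — the implicated sites have <10 reads in at least two of
   the three tumor samples (both sites must fail by default).
4. distal_dominant_tumor — the most distal site holds the plurality of the
   gene's included reads in at least two of the three tumor samples
   (no shift toward the proximal end in the tumors).
5. proximal_dominant_reference — the most proximal site holds the plurality
   in the reference sample (the reference is already truncated).

"Primarily used" is operationalized as a strict plurality of the included
reads; ties are conservative (the rule does not fire).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .model import CurationDecision, GeneModel, GeneSiteTable

RULE_NAMES = ("tandem_transcript", "overlapping_gene", "low_read_support",
              "distal_dominant_tumor", "proximal_dominant_reference")

MIN_IMPLICATED_READS = 10


def usage_shares(table: GeneSiteTable, sample_id: str) -> np.ndarray:
    row = np.asarray(table.row(sample_id), dtype=float)
    total = row.sum()
    return row / total if total > 0 else np.zeros_like(row)


def implicated_sites(table: GeneSiteTable, tumor_samples: Sequence[str],
                     reference_sample: str) -> tuple[int, int]:
    """Column indices of the proximal/distal site pair driving the shift: the
    sites with the largest increase and largest decrease in mean tumor usage
    share relative to the reference, ordered proximal first."""
    tumor_mean = np.mean([usage_shares(table, s) for s in tumor_samples], axis=0)
    delta = tumor_mean - usage_shares(table, reference_sample)
    i, j = int(np.argmax(delta)), int(np.argmin(delta))
    return (i, j) if i < j else (j, i)


def _within_own_gene(pos: int, gene: GeneModel, flank: int) -> bool:
    for tx in gene.transcripts:
        s, e = tx.span
        if s <= pos < e:
            return True
    if gene.strand == "+":
        return gene.start <= pos < gene.end + flank
    return gene.start - flank <= pos < gene.end


def apply_structural_rules(table: GeneSiteTable, gene: GeneModel,
                           all_genes: Sequence[GeneModel],
                           tumor_samples: Sequence[str], reference_sample: str,
                           flank: int = 1000) -> str | None:
    """Rules 1-2 (transcript-containment geometry only)."""
    prox, dist = implicated_sites(table, tumor_samples, reference_sample)
    positions = [table.site_positions[prox], table.site_positions[dist]]
    if not all(_within_own_gene(p, gene, flank) for p in positions):
        return "tandem_transcript"
    for other in all_genes:
        if other.gene_id == gene.gene_id or other.strand != gene.strand \
                or other.chrom != gene.chrom:
            continue
        spans = [tx.span for tx in other.transcripts] or [(other.start, other.end)]
        if any(s <= p < e for p in positions for s, e in spans):
            return "overlapping_gene"
    return None


def apply_read_support_rule(table: GeneSiteTable, tumor_samples: Sequence[str],
                            reference_sample: str,
                            min_reads: int = MIN_IMPLICATED_READS,
                            mode: str = "both") -> str | None:
    """Rule 3: implicated sites underpowered in the tumor group.

    A site "fails" when its count is below ``min_reads`` in at least 2 of the
    3 tumors; with ``mode="both"`` (default) the rule fires only when the
    proximal and the distal implicated site both fail, with ``mode="any"``
    when either does.
    """
    prox, dist = implicated_sites(table, tumor_samples, reference_sample)
    majority = (len(tumor_samples) + 1) // 2  # 2 of 3

    def fails(col: int) -> bool:
        low = sum(1 for s in tumor_samples if table.row(s)[col] < min_reads)
        return low >= majority

    failing = [fails(prox), fails(dist)]
    fired = all(failing) if mode == "both" else any(failing)
    return "low_read_support" if fired else None


def _plurality_column(table: GeneSiteTable, sample_id: str) -> int | None:
    """Column with a strict plurality of the sample's reads, None on a tie."""
    row = np.asarray(table.row(sample_id))
    best = int(np.argmax(row))
    if (row == row[best]).sum() > 1:
        return None
    return best


def apply_truncation_direction_rules(table: GeneSiteTable,
                                     tumor_samples: Sequence[str],
                                     reference_sample: str) -> str | None:
    """Rules 4-5: the shift must run toward the proximal end in the tumors."""
    distal_col = table.n_sites - 1
    n_distal_dominant = sum(
        1 for s in tumor_samples if _plurality_column(table, s) == distal_col)
    if n_distal_dominant >= (len(tumor_samples) + 1) // 2:
        return "distal_dominant_tumor"
    if _plurality_column(table, reference_sample) == 0:
        return "proximal_dominant_reference"
    return None


def curate_gene(table: GeneSiteTable, gene: GeneModel,
                all_genes: Sequence[GeneModel],
                tumor_samples: Sequence[str], reference_sample: str,
                min_reads: int = MIN_IMPLICATED_READS,
                read_support_mode: str = "both",
                flank: int = 1000) -> CurationDecision:
    """Apply rules 1->5 in order; the first firing rule decides."""
    prox, dist = implicated_sites(table, tumor_samples, reference_sample)
    evidence = {
        "implicated_proximal": table.site_positions[prox],
        "implicated_distal": table.site_positions[dist],
        "implicated_tumor_counts": {
            s: [table.row(s)[prox], table.row(s)[dist]] for s in tumor_samples},
    }
    fired = (apply_structural_rules(table, gene, all_genes, tumor_samples,
                                    reference_sample, flank)
             or apply_read_support_rule(table, tumor_samples, reference_sample,
                                        min_reads, read_support_mode)
             or apply_truncation_direction_rules(table, tumor_samples,
                                                 reference_sample))
    return CurationDecision(gene_id=table.gene_id, rule_fired=fired or "none",
                            kept=fired is None, evidence=evidence)


def curate_genes(tables: Mapping[str, GeneSiteTable],
                 significant_gene_ids: Sequence[str],
                 genes_by_id: Mapping[str, GeneModel],
                 tumor_samples: Sequence[str], reference_sample: str,
                 **kwargs) -> dict[str, CurationDecision]:
    """Curation decisions for every significant gene (never adds genes)."""
    all_genes = list(genes_by_id.values())
    return {g: curate_gene(tables[g], genes_by_id[g], all_genes,
                           tumor_samples, reference_sample, **kwargs)
            for g in significant_gene_ids}
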