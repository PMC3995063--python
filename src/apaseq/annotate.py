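"""Genomic classification of polyA sites and site-to-gene association.

Each retained site is placed in exactly one category — 5UTR, CODING, 3UTR
(within a same-strand protein-coding gene), ncGENE (within a non-coding
gene), PROMOTER (<=1 kb upstream of a gene), DOWNSTREAM (<=1 kb downstream),
or INTERGENIC.  Intronic positions and exonic positions within the coding
region are both CODING, since their usage truncates the open reading frame.
Category priority is 3UTR > CODING > 5UTR > ncGENE > PROMOTER > DOWNSTREAM:
a genuine 3'-end annotation wins over an intron of an overlapping isoform,
and the priority applies across all transcripts of a gene.  Overlap is
strand-matched throughout; antisense overlap does not annotate.

Sites up to 1 kb downstream of a gene's 3' end are associated to that gene
and take part in the APA analysis (they behave like unannotated distal
sites); PROMOTER and INTERGENIC sites carry no gene.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import AnnotatedSite, GeneModel, PolyASite, TranscriptModel

DEFAULT_FLANK = 1000


# ---------------------------------------------------------------------------
# GTF reading

def read_gene_models(gtf_path: str) -> list[GeneModel]:
    """Build gene models from a GTF (gene/transcript/exon/CDS features).

    ``gene_biotype`` attributes other than ``protein_coding`` mark non-coding
    genes.  UTRs are derived from exon/CDS geometry, so explicit UTR features
    are not required.
    """
    import pyranges as pr

    with open(gtf_path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    df = pr.read_gtf(gtf_path).df
    if df.empty:
        return []
    genes: list[GeneModel] = []
    for gene_id, gdf in df.groupby("gene_id", sort=True):
        gene_rows = gdf[gdf.Feature == "gene"]
        if len(gene_rows):
            grow = gene_rows.iloc[0]
            start, end = int(grow.Start), int(grow.End)
            biotype = str(grow.get("gene_biotype", "protein_coding"))
            chrom, strand = str(grow.Chromosome), str(grow.Strand)
        else:
            start, end = int(gdf.Start.min()), int(gdf.End.max())
            biotype = "protein_coding"
            chrom, strand = str(gdf.Chromosome.iloc[0]), str(gdf.Strand.iloc[0])
        if biotype != "protein_coding":
            biotype = "non_coding"
        transcripts = []
        tx_df = gdf[gdf.Feature.isin(["exon", "CDS"]) & gdf.transcript_id.notna()]
        for tx_id, tdf in tx_df.groupby("transcript_id", sort=True):
            exons = sorted((int(r.Start), int(r.End))
                           for r in tdf[tdf.Feature == "exon"].itertuples())
            cds_rows = tdf[tdf.Feature == "CDS"]
            cds = None
            if len(cds_rows):
                cds = (int(cds_rows.Start.min()), int(cds_rows.End.max()))
            if exons:
                transcripts.append(TranscriptModel(str(tx_id), exons, cds))
        genes.append(GeneModel(gene_id=str(gene_id), chrom=chrom, strand=strand,
                               start=start, end=end, biotype=biotype,
                               transcripts=transcripts))
    return genes


# ---------------------------------------------------------------------------
# Interval index

class GeneIndex:
    """Per-(chrom, strand) interval lookup of gene spans padded by the flank."""

    def __init__(self, genes: Sequence[GeneModel], flank: int = DEFAULT_FLANK):
        self.flank = flank
        self._trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        for gene in genes:
            self._trees[(gene.chrom, gene.strand)].addi(
                gene.start - flank, gene.end + flank, gene)

    def near(self, chrom: str, strand: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]


def _in_any(pos: int, intervals: Iterable[tuple[int, int]]) -> bool:
    return any(lo <= pos < hi for lo, hi in intervals)


def _gene_category(pos: int, gene: GeneModel) -> str | None:
    """Category of a position inside the gene span, or None if outside."""
    if not (gene.start <= pos < gene.end):
        return None
    if not gene.is_coding:
        return "ncGENE"
    if _in_any(pos, gene.utr3_intervals()):
        return "3UTR"
    if any(tx.cds and tx.cds[0] <= pos < tx.cds[1] for tx in gene.transcripts):
        return "CODING"  # exonic CDS or intron within the coding region
    if _in_any(pos, gene.utr5_intervals()):
        return "5UTR"
    # inside the gene but outside every annotated feature (e.g. an intron
    # flanked by UTR exons): treat as CODING-region context of a coding gene
    return "CODING"


def _downstream_gene(pos: int, genes: Iterable[GeneModel], flank: int) -> GeneModel | None:
    """The same-strand gene whose 3' end is nearest upstream within the flank."""
    best, best_dist = None, None
    for gene in genes:
        end3 = gene.three_prime_end()
        dist = pos - end3 if gene.strand == "+" else end3 - pos
        if 0 < dist <= flank and (best_dist is None or dist < best_dist):
            best, best_dist = gene, dist
    return best


def _upstream_of_gene(pos: int, gene: GeneModel, flank: int) -> bool:
    start5 = gene.start if gene.strand == "+" else gene.end - 1
    dist = start5 - pos if gene.strand == "+" else pos - start5
    return 0 < dist <= flank


_PRIORITY = {"3UTR": 0, "CODING": 1, "5UTR": 2, "ncGENE": 3}


def classify_site(site: PolyASite, index: GeneIndex) -> AnnotatedSite:
    """Assign the category and gene of one site (strand-matched)."""
    candidates = index.near(site.chrom, site.strand, site.position)

    best: tuple[int, str, GeneModel] | None = None
    for gene in candidates:
        cat = _gene_category(site.position, gene)
        if cat is not None and (best is None or _PRIORITY[cat] < best[0]):
            best = (_PRIORITY[cat], cat, gene)
    if best is not None:
        return AnnotatedSite(site=site, category=best[1], gene_id=best[2].gene_id)

    if any(_upstream_of_gene(site.position, g, index.flank) for g in candidates):
        return AnnotatedSite(site=site, category="PROMOTER", gene_id=None)

    gene = _downstream_gene(site.position, candidates, index.flank)
    if gene is not None:
        return AnnotatedSite(site=site, category="DOWNSTREAM", gene_id=gene.gene_id)

    return AnnotatedSite(site=site, category="INTERGENIC", gene_id=None)


def annotate_sites(sites: Iterable[PolyASite], genes: Sequence[GeneModel],
                   flank: int = DEFAULT_FLANK) -> list[AnnotatedSite]:
    index = GeneIndex(genes, flank)
    return [classify_site(site, index) for site in sites]


def category_report(annotated: Iterable[AnnotatedSite]) -> pd.DataFrame:
    """Per-category site counts and mean reads per site (genome-distribution
    summary of the called sites)."""
    rows = [(a.category, a.site.total_reads) for a in annotated]
    df = pd.DataFrame(rows, columns=["category", "reads"])
    if df.empty:
        return pd.DataFrame(columns=["n_sites", "mean_reads"])
    return df.groupby("category")["reads"].agg(n_sites="size", mean_reads="mean")
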