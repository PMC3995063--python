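"""End-to-end orchestration: reads -> QC -> sites -> annotation -> APA calls
-> curation, plus evaluation against a synthetic bundle's ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import annotate, cluster, curation, readqc, stats
from .model import (AnnotatedSite, APAVerdict, CurationDecision, GeneModel,
                    GeneSiteTable, MappedReadEnd, PolyASite, QcThresholds)
from .simulate import FixtureBundle


@dataclass
class PipelineResult:
    qc_stats: dict[str, int]
    sites: list[PolyASite]
    annotated: list[AnnotatedSite]
    tables: dict[str, GeneSiteTable]
    verdicts: dict[str, APAVerdict]
    decisions: dict[str, CurationDecision] = field(default_factory=dict)

    @property
    def significant_genes(self) -> list[str]:
        return sorted(g for g, v in self.verdicts.items() if v.significant)

    @property
    def curated_genes(self) -> list[str]:
        return sorted(g for g, d in self.decisions.items() if d.kept)


def run_pipeline(reads_by_sample: Mapping[str, Sequence[MappedReadEnd]],
                 genome: Mapping[str, str], genes: Sequence[GeneModel],
                 tumor_samples: Sequence[str], reference_sample: str,
                 thresholds: QcThresholds | None = None,
                 gap: int = cluster.DEFAULT_GAP,
                 min_fraction: float = stats.MIN_SITE_FRACTION,
                 fdr_threshold: float = stats.FDR_THRESHOLD,
                 curate: bool = True) -> PipelineResult:
    """Run the whole analysis on already-mapped read 3'-ends."""
    samples = list(tumor_samples) + [reference_sample]
    all_reads = [r for s in samples for r in reads_by_sample.get(s, [])]
    kept, qc_stats = readqc.filter_reads(all_reads, genome, thresholds)
    sites = cluster.call_sites(kept, gap=gap, samples=samples)
    annotated = annotate.annotate_sites(sites, genes)
    coding = {g.gene_id for g in genes if g.is_coding}
    tables = stats.build_gene_tables(annotated, samples, coding_gene_ids=coding,
                                     min_fraction=min_fraction)
    verdicts = stats.test_gene_tables(tables, tumor_samples, reference_sample,
                                      fdr_threshold=fdr_threshold)
    result = PipelineResult(qc_stats=qc_stats, sites=sites, annotated=annotated,
                            tables=tables, verdicts=verdicts)
    if curate:
        genes_by_id = {g.gene_id: g for g in genes}
        result.decisions = curation.curate_genes(
            tables, result.significant_genes, genes_by_id,
            tumor_samples, reference_sample)
    return result


def run_pipeline_on_bundle(bundle: FixtureBundle, **kwargs) -> PipelineResult:
    cfg = bundle.config
    return run_pipeline(bundle.reads, bundle.genome, bundle.genes,
                        cfg.tumor_samples, cfg.reference_sample, **kwargs)


def recovery_metrics(bundle: FixtureBundle, result: PipelineResult) -> dict[str, float]:
    """Sensitivity on planted-shift genes and empirical false-call rate on
    null genes, for the significance call against the bundle's truth."""
    planted = {t.gene_id for t in bundle.truths if t.apa_flag}
    null = {t.gene_id for t in bundle.truths if not t.apa_flag}
    called = set(result.significant_genes)
    sensitivity = len(called & planted) / len(planted) if planted else float("nan")
    false_rate = len(called & null) / len(null) if null else float("nan")
    return {"n_planted": len(planted), "n_null": len(null),
            "n_called": len(called),
            "sensitivity": sensitivity, "false_call_rate": false_rate}
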