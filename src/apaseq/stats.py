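"""Differential polyA-site usage statistics.

For each protein-coding gene with at least two polyA sites we build a
samples x sites read-count contingency table, after excluding sites that
never reach 10% of the gene's reads in any sample.  Differential usage
between two samples is tested with a two-sided Fisher exact test on the
2 x C table of their rows, for every pair of samples.  P-values are adjusted
per sample-pair across genes with Benjamini-Hochberg, and a gene is called
tumor-specific APA when the tumor group is internally homogeneous (all
tumor-tumor q > 0.1) while every tumor differs from the reference
(all tumor-reference q < 0.1).
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .model import AnnotatedSite, APAVerdict, GeneSiteTable

MIN_SITE_FRACTION = 0.10
FDR_THRESHOLD = 0.10
APA_CATEGORIES = ("5UTR", "CODING", "3UTR", "DOWNSTREAM")
MAX_ENUMERATION = 1_000_000
MC_DRAWS = 100_000
MC_SEED = 20140612
_TIE_TOL = 1e-7


# ---------------------------------------------------------------------------
# Gene tables

def build_gene_table(gene_id: str, sites: Sequence[AnnotatedSite],
                     samples: Sequence[str],
                     min_fraction: float = MIN_SITE_FRACTION,
                     require_all_samples: bool = False) -> GeneSiteTable:
    """Contingency table for one gene over its attributed sites.

    A site is included iff its read count reaches ``min_fraction`` of the
    gene's total count in at least one sample (``require_all_samples=True``
    switches to the stricter every-sample variant).  Columns are ordered
    proximal (5') first in transcript orientation.  Reads at excluded sites
    are dropped from the table.
    """
    if not sites:
        return GeneSiteTable(gene_id=gene_id, strand="+", site_positions=[], counts={})
    strand = sites[0].site.strand
    ordered = sorted(sites, key=lambda a: a.site.position, reverse=(strand == "-"))
    totals = {s: sum(a.site.counts.get(s, 0) for a in ordered) for s in samples}

    def passes(a: AnnotatedSite) -> bool:
        checks = (totals[s] > 0 and a.site.counts.get(s, 0) >= min_fraction * totals[s]
                  for s in samples)
        return all(checks) if require_all_samples else any(checks)

    flags = [passes(a) for a in ordered]
    included = [a for a, f in zip(ordered, flags) if f]
    excluded = [a.site.position for a, f in zip(ordered, flags) if not f]
    return GeneSiteTable(
        gene_id=gene_id, strand=strand,
        site_positions=[a.site.position for a in included],
        counts={s: [a.site.counts.get(s, 0) for a in included] for s in samples},
        excluded_positions=excluded)


def build_gene_tables(annotated: Iterable[AnnotatedSite], samples: Sequence[str],
                      coding_gene_ids: set[str] | None = None,
                      min_fraction: float = MIN_SITE_FRACTION) -> dict[str, GeneSiteTable]:
    """Tables for every protein-coding gene with attributed sites (gene-body
    and <=1 kb downstream categories only)."""
    by_gene: dict[str, list[AnnotatedSite]] = {}
    for a in annotated:
        if a.gene_id is None or a.category not in APA_CATEGORIES:
            continue
        if coding_gene_ids is not None and a.gene_id not in coding_gene_ids:
            continue
        by_gene.setdefault(a.gene_id, []).append(a)
    return {g: build_gene_table(g, sites, samples, min_fraction)
            for g, sites in sorted(by_gene.items())}


# ---------------------------------------------------------------------------
# Fisher exact test for 2 x C tables

def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _enumeration_size(col_sums: np.ndarray, r1: int) -> float:
    return float(np.prod([min(int(c), r1) + 1.0 for c in col_sums]))


def _exact_2xc(row_a: np.ndarray, col_sums: np.ndarray) -> float:
    """Full enumeration over 2 x C tables with the observed margins.

    The two-sided p-value is the total null probability of tables no more
    probable than the observed one (relative tie tolerance 1e-7), under the
    multivariate hypergeometric null with fixed margins.
    """
    r1 = int(row_a.sum())
    n = int(col_sums.sum())
    log_denom = _log_binom(n, r1)
    log_p_obs = float(np.sum(_log_binom(col_sums, row_a)) - log_denom)

    # build all admissible first rows column by column, pruning partial sums
    sums = np.zeros(1, dtype=np.int64)
    logp = np.zeros(1)
    remaining = np.concatenate([np.cumsum(col_sums[::-1])[::-1][1:], [0]])
    for j, c in enumerate(col_sums):
        a = np.arange(min(int(c), r1) + 1)
        new_sums = (sums[:, None] + a[None, :]).ravel()
        new_logp = (logp[:, None] + _log_binom(int(c), a)[None, :]).ravel()
        keep = (new_sums <= r1) & (new_sums + remaining[j] >= r1)
        sums, logp = new_sums[keep], new_logp[keep]
    logp = logp[sums == r1] - log_denom
    mask = logp <= log_p_obs + math.log1p(_TIE_TOL)
    return float(min(1.0, np.exp(logp[mask]).sum()))


def _montecarlo_2xc(row_a: np.ndarray, col_sums: np.ndarray,
                    draws: int, seed: int) -> float:
    r1 = int(row_a.sum())
    n = int(col_sums.sum())
    log_denom = _log_binom(n, r1)
    log_p_obs = float(np.sum(_log_binom(col_sums, row_a)) - log_denom)
    rng = np.random.default_rng(seed)
    tables = rng.multivariate_hypergeometric(col_sums.astype(np.int64), r1, size=draws)
    log_p = np.sum(_log_binom(col_sums[None, :], tables), axis=1) - log_denom
    return float(np.mean(log_p <= log_p_obs + math.log1p(_TIE_TOL)))


def fisher_exact_2xc(row_a: Sequence[int], row_b: Sequence[int],
                     max_enumeration: int = MAX_ENUMERATION,
                     mc_draws: int = MC_DRAWS, mc_seed: int = MC_SEED) -> float:
    """Two-sided Fisher exact p-value for a 2 x C contingency table.

    Exact by full enumeration of tables with the observed margins whenever
    the enumeration size is at most ``max_enumeration``; otherwise a
    Monte-Carlo estimate with ``mc_draws`` draws from the fixed-margin null
    (fixed seed, so results are reproducible).  Degenerate tables (a zero
    row, or fewer than two non-empty columns) return p = 1.
    """
    a = np.asarray(row_a, dtype=np.int64)
    b = np.asarray(row_b, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("rows must be equal-length vectors over >=2 sites")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    col_sums = a + b
    nonzero = col_sums > 0
    a, col_sums = a[nonzero], col_sums[nonzero]
    if a.sum() == 0 or b.sum() == 0 or len(col_sums) < 2:
        return 1.0
    if _enumeration_size(col_sums, int(a.sum())) <= max_enumeration:
        return _exact_2xc(a, col_sums)
    return _montecarlo_2xc(a, col_sums, mc_draws, mc_seed)


# ---------------------------------------------------------------------------
# Multiple-testing correction and the group-consistency call

def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def sample_pairs(tumor_samples: Sequence[str], reference_sample: str
                 ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    within = list(itertools.combinations(tumor_samples, 2))
    versus = [(t, reference_sample) for t in tumor_samples]
    return within, versus


def test_gene_tables(tables: Mapping[str, GeneSiteTable],
                     tumor_samples: Sequence[str], reference_sample: str,
                     fdr_threshold: float = FDR_THRESHOLD,
                     **fisher_kwargs) -> dict[str, APAVerdict]:
    """Pairwise Fisher tests for every testable gene, BH correction per
    sample pair across genes, then the group-consistency call."""
    within, versus = sample_pairs(tumor_samples, reference_sample)
    pairs = within + versus
    testable = [g for g, t in tables.items() if t.testable]

    p_by_pair: dict[tuple[str, str], np.ndarray] = {}
    for pair in pairs:
        p_by_pair[pair] = np.array([
            fisher_exact_2xc(tables[g].row(pair[0]), tables[g].row(pair[1]),
                             **fisher_kwargs)
            for g in testable])
    q_by_pair = {pair: bh_fdr(p_by_pair[pair]) for pair in pairs}

    verdicts: dict[str, APAVerdict] = {}
    for i, g in enumerate(testable):
        p = {pair: float(p_by_pair[pair][i]) for pair in pairs}
        q = {pair: float(q_by_pair[pair][i]) for pair in pairs}
        verdicts[g] = APAVerdict(
            gene_id=g, p_values=p, q_values=q,
            significant=call_apa_gene(q, within, versus, fdr_threshold))
    for g, t in tables.items():
        if not t.testable:
            verdicts[g] = APAVerdict(gene_id=g, p_values={}, q_values={},
                                     significant=False, testable=False)
    return verdicts


def call_apa_gene(q_values: Mapping[tuple[str, str], float],
                  within_pairs: Sequence[tuple[str, str]],
                  versus_pairs: Sequence[tuple[str, str]],
                  fdr_threshold: float = FDR_THRESHOLD) -> bool:
    """Tumor-specific APA call: homogeneous tumor group (all within-group
    q > threshold) and all tumor-vs-reference pairs significant
    (q < threshold).  Any missing pair makes the gene untestable (False)."""
    try:
        within_q = [q_values[p] for p in within_pairs]
        versus_q = [q_values[p] for p in versus_pairs]
    except KeyError:
        return False
    return (all(q > fdr_threshold for q in within_q)
            and all(q < fdr_threshold for q in versus_q))


# ---------------------------------------------------------------------------
# Isoform ratios from read counts

def count_isoform_ratio(table: GeneSiteTable, proximal: int, distal: int,
                        sample_id: str) -> float:
    """Short/long isoform read-count ratio (proximal / distal counts) for one
    sample; +inf when only the proximal site has reads, NaN when neither
    has reads."""
    for pos in (proximal, distal):
        if pos not in table.site_positions:
            raise ValueError(f"site {pos} not in gene table {table.gene_id}")
    row = table.row(sample_id)
    p = row[table.site_positions.index(proximal)]
    d = row[table.site_positions.index(distal)]
    if d == 0:
        return math.inf if p > 0 else math.nan
    return p / d
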