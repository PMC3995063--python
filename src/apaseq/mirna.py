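"""miRNA target-site loss caused by 3'UTR shortening.

A gene that shifts usage from a distal to a proximal 3'UTR polyA site
produces mRNAs lacking the UTR segment between the two cleavage positions,
and with it any miRNA target sites located there.  Targets are intersected
with the set of miRNAs actually expressed in the tumor type (by default,
detected in at least 4 of 5 profiled samples), since only those losses can
de-repress the mRNA.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .model import GeneModel, LossReport, MirnaTargetSite

DEFAULT_MIN_DETECTED = 4


def read_target_bed(path: str) -> list[MirnaTargetSite]:
    """Target-site intervals from BED6 (name = miRNA id).  The file is
    expected to be pre-filtered to conserved, well-scoring predictions."""
    targets = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            targets.append(MirnaTargetSite(mirna_id=name, chrom=chrom,
                                           start=int(start), end=int(end),
                                           strand=strand))
    return targets


def read_expressed_mirnas(path: str) -> set[str]:
    """Plain-text list, one miRNA id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def expressed_from_profiles(profiles: pd.DataFrame,
                            min_detected: int = DEFAULT_MIN_DETECTED) -> set[str]:
    """Expressed miRNAs from a detection matrix (rows = miRNAs, columns =
    samples; nonzero/True = detected): detected in >= ``min_detected``
    samples."""
    detected = (profiles.astype(float) > 0).sum(axis=1)
    return set(detected.index[detected >= min_detected])


def truncated_region(gene_strand: str, proximal_pos: int, distal_pos: int) -> tuple[int, int]:
    """Genomic half-open interval transcribed in the long isoform but absent
    from the short one (exclusive of the proximal cleavage base, inclusive of
    the distal one)."""
    if gene_strand == "+":
        if proximal_pos >= distal_pos:
            raise ValueError("proximal site must be 5' of the distal site")
        return proximal_pos + 1, distal_pos + 1
    if proximal_pos <= distal_pos:
        raise ValueError("proximal site must be 5' of the distal site")
    return distal_pos, proximal_pos


def lost_mirna_targets(gene: GeneModel, proximal_pos: int, distal_pos: int,
                       targets: Iterable[MirnaTargetSite],
                       expressed: set[str],
                       straddle_lost: bool = True) -> LossReport:
    """Target sites lost when cleavage moves from the distal to the proximal
    site.

    A target is lost when it is present in the long isoform but not in the
    short one.  With ``straddle_lost=True`` (default) a target straddling the
    proximal cleavage position counts as lost — the short isoform cannot
    present the full site, and a partial seed match is non-functional.  With
    ``straddle_lost=False`` only targets fully contained in the truncated
    region count.
    """
    lo, hi = truncated_region(gene.strand, proximal_pos, distal_pos)
    lost: list[MirnaTargetSite] = []
    for t in targets:
        if t.chrom != gene.chrom or t.strand != gene.strand:
            continue
        if gene.strand == "+":
            in_long = t.end <= hi          # entirely 5' of (and incl.) distal
            in_short = t.end <= lo         # entirely 5' of (and incl.) proximal
        else:
            in_long = t.start >= lo
            in_short = t.start >= hi
        if straddle_lost:
            if in_long and not in_short:
                lost.append(t)
        else:
            if lo <= t.start and t.end <= hi:
                lost.append(t)
    lost_expressed = [t for t in lost if t.mirna_id in expressed]
    return LossReport(gene_id=gene.gene_id, region=(lo, hi), lost=lost,
                      lost_expressed=lost_expressed)


def loss_table(reports: Sequence[LossReport]) -> pd.DataFrame:
    """Per-gene summary of lost sites and lost sites for expressed miRNAs."""
    rows = []
    for r in reports:
        rows.append({
            "gene_id": r.gene_id,
            "truncated_start": r.region[0],
            "truncated_end": r.region[1],
            "n_lost_sites": len(r.lost),
            "n_lost_expressed": len(r.lost_expressed),
            "lost_expressed_mirnas": ",".join(
                sorted({t.mirna_id for t in r.lost_expressed})),
        })
    return pd.DataFrame(rows)
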