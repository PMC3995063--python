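"""PolyA-site calling: single-linkage clustering of read 3' ends and the
cross-sample retention rule.

Cleavage is imprecise within a few nucleotides, so read ends belonging to one
polyA site scatter around it.  Read ends on the same (chromosome, strand) are
merged single-linkage whenever consecutive positions are < 24 nt apart; the
site coordinate is the read-weighted median of the cluster, and a site is
retained when it has at least one read in at least two samples or two or more
reads in total.  Clustering pools reads across all samples so that every
sample's counts refer to one unified site registry.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .model import CleavageCluster, MappedReadEnd, PolyASite

DEFAULT_GAP = 24


def cluster_positions(read_ends: Iterable[MappedReadEnd], gap: int = DEFAULT_GAP) -> list[CleavageCluster]:
    """Single-linkage clustering per (chrom, strand) with a strict ``< gap``
    merge criterion between read positions.

    Two read ends share a cluster iff they are connected by a chain of
    pairwise distances < gap; clusters are maximal.  Per-sample counts are
    retained per member position.  The result is independent of input order.
    """
    by_key: dict[tuple[str, str], dict[int, dict[str, int]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(int)))
    for read in read_ends:
        by_key[(read.chrom, read.strand)][read.cleavage_pos][read.sample_id] += 1

    clusters: list[CleavageCluster] = []
    for (chrom, strand) in sorted(by_key):
        members = by_key[(chrom, strand)]
        positions = np.array(sorted(members))
        # break points where the gap between consecutive distinct positions
        # reaches the threshold (criterion is "< gap apart" to merge)
        breaks = np.nonzero(np.diff(positions) >= gap)[0] + 1
        for chunk in np.split(positions, breaks):
            clusters.append(CleavageCluster(
                chrom=chrom, strand=strand,
                members={int(p): dict(members[int(p)]) for p in chunk}))
    return clusters


def representative_position(cluster: CleavageCluster) -> int:
    """Read-weighted median position of the cluster (each read counted once);
    for an even total read count the lower of the two central values, so the
    representative is always an observed read position."""
    if not cluster.members:
        raise ValueError("empty cluster has no representative position")
    positions = sorted(cluster.members)
    weights = np.array([sum(cluster.members[p].values()) for p in positions])
    total = int(weights.sum())
    if total == 0:
        raise ValueError("cluster with zero reads has no representative position")
    # 0-based rank of the lower median in the expanded, sorted read list
    target_rank = (total + 1) // 2
    cum = np.cumsum(weights)
    return positions[int(np.searchsorted(cum, target_rank))]


def sites_from_clusters(clusters: Sequence[CleavageCluster],
                        samples: Sequence[str] | None = None) -> list[PolyASite]:
    """Collapse each cluster to a PolyASite at its representative position,
    summing member counts per sample. ``samples`` fixes the count keys (zeros
    included) so downstream tables have a consistent sample set."""
    sites = []
    for i, cluster in enumerate(clusters):
        counts: dict[str, int] = {s: 0 for s in samples} if samples else {}
        for per_sample in cluster.members.values():
            for sample_id, n in per_sample.items():
                counts[sample_id] = counts.get(sample_id, 0) + n
        sites.append(PolyASite(
            chrom=cluster.chrom, strand=cluster.strand,
            position=representative_position(cluster),
            counts=counts, site_id=f"site_{i:06d}"))
    return sites


def retain_sites(sites: Iterable[PolyASite]) -> list[PolyASite]:
    """Keep a site iff it has >=1 read in >=2 samples, or >=2 reads in total.

    Singleton sites seen in only one sample are discarded; infrequently used
    sites supported by independent samples (1+1) or by repeated reads are
    kept.
    """
    return [s for s in sites if s.samples_with_reads() >= 2 or s.total_reads >= 2]


def call_sites(read_ends: Iterable[MappedReadEnd], gap: int = DEFAULT_GAP,
               samples: Sequence[str] | None = None) -> list[PolyASite]:
    """Cluster -> representative position -> retention, in one call."""
    return retain_sites(sites_from_clusters(cluster_positions(read_ends, gap), samples))
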