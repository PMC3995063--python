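"""Synthetic 3'-end sequencing fixture bundles with known ground truth.

The generator emulates the data regime the pipeline is built for: a small
genome of protein-coding genes (two exons, one intron, a 3'UTR), each with
2-4 polyA sites placed in the intron, the last-exon 3'UTR, or up to 1 kb
downstream of the gene; multi-sample read 3'-end counts at those sites
(negative-binomial gene totals, multinomial site choice); cleavage-position
jitter of a few nucleotides; internal-priming decoy reads relocated to
planted genomic A-runs; and a planted proximal-shift APA effect in a subset
of genes between a three-sample "tumor" group and a single reference sample.

Every quantity is driven by one integer seed: the reference (genome,
annotation, truth) uses one stream, and each sample's reads use an
independent (seed, sample) stream, so samples are individually reproducible.

Geometry guarantees that make truth evaluation exact: sites within a gene
are >=250 nt apart while jitter is truncated to +/-10 nt, so each true site
maps to exactly one read cluster at the <24 nt clustering gap; the genomic
context around every true site is rewritten A-free, so no true-site read can
fire the internal-priming filter; decoys sit >=100 nt from every true site
and carry a 10-adenine run on the transcribed strand, so every decoy read
fires it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import GeneModel, MappedReadEnd, MirnaTargetSite, TranscriptModel

# gene template, transcript-local coordinates (0 = transcription start)
_GENE_LEN = 2300
_EXON1 = (0, 300)
_INTRON = (300, 1300)
_EXON2 = (1300, 2300)
_CDS_LOCAL = ((100, 300), (1300, 1500))  # per-exon CDS pieces
_SITE_INTRONIC = 700
_SITE_UTR = (1600, 1850, 2100)
_SITE_DOWNSTREAM = 2800
_DECOY_LOCAL = 1000
_GENE_PITCH = 7000
_GENES_PER_CHROM = 100
_CHROM_PAD = 2000
_JITTER_TRUNC = 10
_SAFE_HALFWIDTH = 21  # A-free rewrite half-width around each true site


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulation.

    Defaults describe the benchmark regime used throughout the test suite:
    500 genes with 2-4 polyA sites each, ~300 reads per gene per sample
    (negative binomial, dispersion 0.1), 10% of genes with a planted
    proximal shift (tumor proximal usage 0.8 against 0.2 in the reference),
    2 nt cleavage jitter and a 5% internal-priming rate.
    """

    n_genes: int = 500
    sites_per_gene: tuple[int, int] = (2, 4)
    reads_per_gene_per_sample: float = 300.0
    nb_dispersion: float = 0.1
    apa_gene_fraction: float = 0.10
    proximal_fraction_tumor: float = 0.8
    proximal_fraction_reference: float = 0.2
    cleavage_jitter_sd: float = 2.0
    internal_priming_rate: float = 0.05
    intronic_proximal_fraction: float = 0.4
    qc_fail_fraction: float = 0.0
    seed: int = 0
    tumor_samples: tuple[str, ...] = ("NE_MTT", "NE_CT1", "NE_2TC")
    reference_sample: str = "PIT"

    def __post_init__(self) -> None:
        for name in ("apa_gene_fraction", "proximal_fraction_tumor",
                     "proximal_fraction_reference", "internal_priming_rate",
                     "intronic_proximal_fraction", "qc_fail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.sites_per_gene
        if not (2 <= lo <= hi <= 4):
            raise ValueError("sites_per_gene must be a range within 2..4")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")

    @property
    def samples(self) -> tuple[str, ...]:
        return self.tumor_samples + (self.reference_sample,)


@dataclass
class GroundTruth:
    """Planted truth for one gene: ordered (proximal first, transcript
    orientation) genomic site positions, their kinds, per-sample usage
    fractions (summing to 1), and whether a tumor/reference shift was
    planted."""

    gene_id: str
    chrom: str
    strand: str
    site_positions: list[int]
    site_kinds: list[str]  # intronic | last-exon-3UTR | downstream
    usage: dict[str, list[float]]
    apa_flag: bool
    decoy_position: int


@dataclass
class FixtureBundle:
    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    truths: list[GroundTruth]
    reads: dict[str, list[MappedReadEnd]] = field(default_factory=dict)
    mirna_targets: list[MirnaTargetSite] = field(default_factory=list)
    expressed_mirnas: set[str] = field(default_factory=set)

    @property
    def decoy_positions(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = {}
        for t in self.truths:
            out.setdefault(t.chrom, set()).add(t.decoy_position)
        return out


def _local_to_genomic(local: int, gene_start: int, strand: str) -> int:
    if strand == "+":
        return gene_start + local
    return gene_start + _GENE_LEN - 1 - local


def _local_interval_to_genomic(lo: int, hi: int, gene_start: int, strand: str
                               ) -> tuple[int, int]:
    if strand == "+":
        return gene_start + lo, gene_start + hi
    gene_end = gene_start + _GENE_LEN
    return gene_end - hi, gene_end - lo


def _gene_layout(index: int) -> tuple[str, int, str]:
    chrom = f"chr{index // _GENES_PER_CHROM + 1}"
    slot = index % _GENES_PER_CHROM
    start = _CHROM_PAD + slot * _GENE_PITCH
    strand = "+" if index % 2 == 0 else "-"
    return chrom, start, strand


def _build_gene_model(gene_id: str, chrom: str, start: int, strand: str) -> GeneModel:
    exons = [_local_interval_to_genomic(*_EXON1, start, strand),
             _local_interval_to_genomic(*_EXON2, start, strand)]
    cds_pieces = [_local_interval_to_genomic(lo, hi, start, strand)
                  for lo, hi in _CDS_LOCAL]
    cds = (min(lo for lo, _ in cds_pieces), max(hi for _, hi in cds_pieces))
    tx = TranscriptModel(transcript_id=f"{gene_id}.t1", exons=sorted(exons), cds=cds)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     start=start, end=start + _GENE_LEN,
                     biotype="protein_coding", transcripts=[tx])


def _plant(seq: bytearray, start: int, text: bytes) -> None:
    seq[max(start, 0):start + len(text)] = text[max(-start, 0):]


def generate_reference(config: SimConfig) -> FixtureBundle:
    """Genome, gene models, planted truths and decoys — fully determined by
    the seed; no reads yet."""
    rng = np.random.default_rng([config.seed, 0])
    n_chroms = max(1, -(-config.n_genes // _GENES_PER_CHROM)) if config.n_genes else 0
    chrom_len = _CHROM_PAD * 2 + _GENES_PER_CHROM * _GENE_PITCH
    genome_raw: dict[str, bytearray] = {}
    for c in range(n_chroms):
        bases = rng.integers(0, 4, size=chrom_len)
        genome_raw[f"chr{c + 1}"] = bytearray(
            np.frombuffer(b"ACGT", dtype=np.uint8)[bases].tobytes())

    safe = (b"CGT" * (_SAFE_HALFWIDTH * 2))[: 2 * _SAFE_HALFWIDTH + 1]
    genes: list[GeneModel] = []
    truths: list[GroundTruth] = []
    for g in range(config.n_genes):
        gene_id = f"gene{g:04d}"
        chrom, start, strand = _gene_layout(g)
        genes.append(_build_gene_model(gene_id, chrom, start, strand))

        k = int(rng.integers(config.sites_per_gene[0], config.sites_per_gene[1] + 1))
        intronic = bool(rng.random() < config.intronic_proximal_fraction)
        locals_kinds = [(_SITE_INTRONIC, "intronic") if intronic
                        else (_SITE_UTR[0], "last-exon-3UTR")]
        extras = {2: [(_SITE_UTR[2], "last-exon-3UTR")],
                  3: [(_SITE_UTR[1], "last-exon-3UTR"),
                      (_SITE_UTR[2], "last-exon-3UTR")],
                  4: [(_SITE_UTR[1], "last-exon-3UTR"),
                      (_SITE_UTR[2], "last-exon-3UTR"),
                      (_SITE_DOWNSTREAM, "downstream")]}
        locals_kinds += extras[k]
        positions = [_local_to_genomic(lp, start, strand) for lp, _ in locals_kinds]
        kinds = [kind for _, kind in locals_kinds]

        apa = bool(rng.random() < config.apa_gene_fraction)
        usage: dict[str, list[float]] = {}
        if apa:
            for s in config.tumor_samples:
                p = config.proximal_fraction_tumor
                usage[s] = [p] + [(1 - p) / (k - 1)] * (k - 1)
            p = config.proximal_fraction_reference
            usage[config.reference_sample] = [p] + [(1 - p) / (k - 1)] * (k - 1)
        else:
            shared = rng.dirichlet([2.0] * k).tolist()
            usage = {s: list(shared) for s in config.samples}

        # A-free context around every true site: jittered reads never look
        # internally primed
        seq = genome_raw[chrom]
        for pos in positions:
            _plant(seq, pos - _SAFE_HALFWIDTH, safe)
        # decoy: 10 adenines on the transcribed strand right after the decoy
        # cleavage position
        decoy = _local_to_genomic(_DECOY_LOCAL, start, strand)
        if strand == "+":
            _plant(seq, decoy + 1, b"A" * 10)
        else:
            _plant(seq, decoy - 10, b"T" * 10)

        truths.append(GroundTruth(gene_id=gene_id, chrom=chrom, strand=strand,
                                  site_positions=positions, site_kinds=kinds,
                                  usage=usage, apa_flag=apa,
                                  decoy_position=decoy))

    genome = {c: s.decode("ascii") for c, s in genome_raw.items()}
    bundle = FixtureBundle(config=config, genome=genome, genes=genes, truths=truths)
    _plant_mirna_targets(bundle)
    return bundle


def _plant_mirna_targets(bundle: FixtureBundle) -> None:
    """For every gene whose proximal and distal sites are both in the 3'UTR,
    plant one target fully inside the truncatable region for an expressed
    miRNA, one for an unexpressed miRNA, and one expressed target retained in
    the short isoform."""
    genes_by_id = {g.gene_id: g for g in bundle.genes}
    for truth in bundle.truths:
        gene = genes_by_id[truth.gene_id]

        def to_local(pos: int) -> int:
            if truth.strand == "+":
                return pos - gene.start
            return gene.start + _GENE_LEN - 1 - pos

        utr_local = sorted(to_local(p)
                           for p, kind in zip(truth.site_positions, truth.site_kinds)
                           if kind == "last-exon-3UTR")
        if len(utr_local) < 2:
            continue
        prox, dist = utr_local[0], utr_local[-1]
        # 22-nt targets: one lost between the cleavage sites (expressed), one
        # lost but unexpressed, one retained 5' of the proximal site
        for lo_local, mirna, expressed in (
                (prox + 30, f"mir-lost-{truth.gene_id}", True),
                (prox + 100, f"mir-unexpr-{truth.gene_id}", False),
                (prox - 80, f"mir-kept-{truth.gene_id}", True)):
            assert lo_local + 22 <= dist or lo_local < prox
            s, e = _local_interval_to_genomic(lo_local, lo_local + 22,
                                              gene.start, truth.strand)
            bundle.mirna_targets.append(MirnaTargetSite(
                mirna_id=mirna, chrom=truth.chrom, start=s, end=e,
                strand=truth.strand))
            if expressed:
                bundle.expressed_mirnas.add(mirna)


def simulate_sample_reads(bundle: FixtureBundle, sample_id: str) -> list[MappedReadEnd]:
    """Read 3'-ends for one sample.

    Per gene: total reads ~ NB(mean, dispersion); each read's site chosen
    multinomially from the sample's usage fractions; cleavage position =
    site + rounded Gaussian jitter truncated to +/-10 nt; a fraction
    ``internal_priming_rate`` of reads is relocated (un-jittered) to the
    gene's decoy; reads carry length >=21, score >=4 and unique=True except
    for an optional ``qc_fail_fraction``.
    """
    config = bundle.config
    if sample_id not in config.samples:
        raise ValueError(f"unknown sample {sample_id!r}")
    sample_index = config.samples.index(sample_id)
    rng = np.random.default_rng([config.seed, 1, sample_index])

    mean, disp = config.reads_per_gene_per_sample, config.nb_dispersion
    reads: list[MappedReadEnd] = []
    for truth in bundle.truths:
        if disp > 0:
            r = 1.0 / disp
            n = int(rng.negative_binomial(r, r / (r + mean)))
        else:
            n = int(rng.poisson(mean))
        if n == 0:
            continue
        site_choice = rng.multinomial(n, truth.usage[sample_id])
        positions = np.repeat(truth.site_positions, site_choice)
        if config.cleavage_jitter_sd > 0:
            jitter = np.rint(rng.normal(0, config.cleavage_jitter_sd, size=n))
            positions = positions + np.clip(jitter, -_JITTER_TRUNC, _JITTER_TRUNC).astype(int)
        if config.internal_priming_rate > 0:
            primed = rng.random(n) < config.internal_priming_rate
            positions = np.where(primed, truth.decoy_position, positions)
        lengths = rng.integers(21, 61, size=n)
        scores = rng.integers(4, 11, size=n)
        fail = (rng.random(n) < config.qc_fail_fraction
                if config.qc_fail_fraction > 0 else np.zeros(n, dtype=bool))
        for i in range(n):
            reads.append(MappedReadEnd(
                chrom=truth.chrom, cleavage_pos=int(positions[i]),
                strand=truth.strand, sample_id=sample_id,
                read_length=15 if fail[i] else int(lengths[i]),
                map_score=float(scores[i]), unique=not fail[i]))
    return reads


def generate_bundle(config: SimConfig) -> FixtureBundle:
    """Reference plus reads for every sample."""
    bundle = generate_reference(config)
    for sample_id in config.samples:
        bundle.reads[sample_id] = simulate_sample_reads(bundle, sample_id)
    return bundle


# ---------------------------------------------------------------------------
# Bundle I/O (plain-text formats only)

_MANIFEST = "manifest.yaml"


def write_fixture_bundle(bundle: FixtureBundle, directory: str | Path) -> dict:
    """Write FASTA, GTF, per-sample BED6+2, miRNA target BED, expressed-miRNA
    list, ground-truth TSV and a YAML manifest; returns the manifest dict.
    The directory must already exist (no partial output is produced)."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {directory}")

    with open(directory / "genome.fa", "w") as fh:
        for chrom in sorted(bundle.genome):
            fh.write(f">{chrom}\n")
            seq = bundle.genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")

    with open(directory / "annotation.gtf", "w") as fh:
        for gene in bundle.genes:
            attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            fh.write("\t".join([gene.chrom, "apaseq_sim", "gene",
                                str(gene.start + 1), str(gene.end), ".",
                                gene.strand, ".", attrs]) + "\n")
            for tx in gene.transcripts:
                tattrs = attrs + f' transcript_id "{tx.transcript_id}";'
                s, e = tx.span
                fh.write("\t".join([gene.chrom, "apaseq_sim", "transcript",
                                    str(s + 1), str(e), ".", gene.strand, ".",
                                    tattrs]) + "\n")
                for es, ee in tx.exons:
                    fh.write("\t".join([gene.chrom, "apaseq_sim", "exon",
                                        str(es + 1), str(ee), ".", gene.strand,
                                        ".", tattrs]) + "\n")
                if tx.cds is not None:
                    for es, ee in tx.exons:
                        lo, hi = max(es, tx.cds[0]), min(ee, tx.cds[1])
                        if lo < hi:
                            fh.write("\t".join([gene.chrom, "apaseq_sim", "CDS",
                                                str(lo + 1), str(hi), ".",
                                                gene.strand, "0", tattrs]) + "\n")

    read_files = {}
    for sample_id, reads in bundle.reads.items():
        path = directory / f"reads_{sample_id}.bed"
        read_files[sample_id] = path.name
        with open(path, "w") as fh:
            for i, r in enumerate(reads):
                fh.write("\t".join([
                    r.chrom, str(r.cleavage_pos), str(r.cleavage_pos + 1),
                    f"{sample_id}:read{i:07d}", str(r.map_score), r.strand,
                    str(r.read_length), "1" if r.unique else "0"]) + "\n")

    with open(directory / "mirna_targets.bed", "w") as fh:
        for t in bundle.mirna_targets:
            fh.write("\t".join([t.chrom, str(t.start), str(t.end),
                                t.mirna_id, "0", t.strand]) + "\n")
    with open(directory / "expressed_mirnas.txt", "w") as fh:
        for mirna in sorted(bundle.expressed_mirnas):
            fh.write(mirna + "\n")

    truth_rows = []
    for t in bundle.truths:
        row = {"gene_id": t.gene_id, "chrom": t.chrom, "strand": t.strand,
               "apa_flag": int(t.apa_flag),
               "site_positions": ",".join(map(str, t.site_positions)),
               "site_kinds": ",".join(t.site_kinds),
               "decoy_position": t.decoy_position}
        for s in bundle.config.samples:
            row[f"usage_{s}"] = ",".join(f"{u:.17g}" for u in t.usage[s])
        truth_rows.append(row)
    truth_cols = (["gene_id", "chrom", "strand", "apa_flag", "site_positions",
                   "site_kinds", "decoy_position"]
                  + [f"usage_{s}" for s in bundle.config.samples])
    pd.DataFrame(truth_rows, columns=truth_cols).to_csv(
        directory / "ground_truth.tsv", sep="\t", index=False)

    manifest = {
        "config": dataclasses.asdict(bundle.config),
        "files": {"genome": "genome.fa", "annotation": "annotation.gtf",
                  "reads": read_files, "mirna_targets": "mirna_targets.bed",
                  "expressed_mirnas": "expressed_mirnas.txt",
                  "ground_truth": "ground_truth.tsv"},
    }
    with open(directory / _MANIFEST, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def read_fixture_bundle(directory: str | Path) -> FixtureBundle:
    """Reconstruct a bundle from the files written by write_fixture_bundle."""
    from Bio import SeqIO

    from .annotate import read_gene_models
    from .mirna import read_expressed_mirnas, read_target_bed

    directory = Path(directory)
    with open(directory / _MANIFEST) as fh:
        manifest = yaml.safe_load(fh)
    cfg = dict(manifest["config"])
    cfg["sites_per_gene"] = tuple(cfg["sites_per_gene"])
    cfg["tumor_samples"] = tuple(cfg["tumor_samples"])
    config = SimConfig(**cfg)

    genome = {rec.id: str(rec.seq)
              for rec in SeqIO.parse(directory / "genome.fa", "fasta")}
    genes = read_gene_models(str(directory / "annotation.gtf"))

    truths = []
    truth_df = pd.read_csv(directory / "ground_truth.tsv", sep="\t",
                           dtype={"site_positions": str, "site_kinds": str})
    truth_df = truth_df.dropna(how="all")
    for row in truth_df.itertuples():
        usage = {s: [float(x) for x in getattr(row, f"usage_{s}").split(",")]
                 for s in config.samples}
        truths.append(GroundTruth(
            gene_id=row.gene_id, chrom=row.chrom, strand=row.strand,
            site_positions=[int(x) for x in row.site_positions.split(",")],
            site_kinds=row.site_kinds.split(","), usage=usage,
            apa_flag=bool(row.apa_flag), decoy_position=int(row.decoy_position)))

    reads: dict[str, list[MappedReadEnd]] = {}
    for sample_id, fname in manifest["files"]["reads"].items():
        sample_reads = []
        with open(directory / fname) as fh:
            for line in fh:
                chrom, start, _end, _name, score, strand, length, unique = \
                    line.rstrip("\n").split("\t")
                sample_reads.append(MappedReadEnd(
                    chrom=chrom, cleavage_pos=int(start), strand=strand,
                    sample_id=sample_id, read_length=int(length),
                    map_score=float(score), unique=unique == "1"))
        reads[sample_id] = sample_reads

    return FixtureBundle(
        config=config, genome=genome, genes=genes, truths=truths, reads=reads,
        mirna_targets=read_target_bed(str(directory / "mirna_targets.bed")),
        expressed_mirnas=read_expressed_mirnas(str(directory / "expressed_mirnas.txt")))
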