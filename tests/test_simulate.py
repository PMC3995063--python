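"""Synthetic fixture bundles: determinism, noise model, planted structure."""

import re

import numpy as np
import pytest

from apaseq.readqc import is_internal_priming, priming_context
from apaseq.simulate import (SimConfig, generate_bundle, generate_reference,
                             read_fixture_bundle, simulate_sample_reads,
                             write_fixture_bundle)


def test_reference_is_deterministic_by_seed(tmp_path):
    cfg = SimConfig(n_genes=10, seed=1)
    a, b = generate_reference(cfg), generate_reference(cfg)
    assert a.genome == b.genome
    assert a.genes == b.genes
    assert a.truths == b.truths
    (tmp_path / "x").mkdir(), (tmp_path / "y").mkdir()
    write_fixture_bundle(a, tmp_path / "x")
    write_fixture_bundle(b, tmp_path / "y")
    for name in ("genome.fa", "annotation.gtf"):
        assert (tmp_path / "x" / name).read_bytes() \
            == (tmp_path / "y" / name).read_bytes()


def test_different_seed_changes_output():
    assert generate_reference(SimConfig(n_genes=5, seed=1)).genome \
        != generate_reference(SimConfig(n_genes=5, seed=2)).genome


def test_empty_gene_set(tmp_path):
    bundle = generate_bundle(SimConfig(n_genes=0, seed=1))
    assert bundle.genes == [] and bundle.truths == []
    write_fixture_bundle(bundle, tmp_path)
    back = read_fixture_bundle(tmp_path)
    assert back.genes == [] and back.truths == []


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimConfig(apa_gene_fraction=1.5)
    with pytest.raises(ValueError):
        SimConfig(sites_per_gene=(1, 4))
    with pytest.raises(ValueError):
        SimConfig(n_genes=-1)


def test_planted_decoys_flagged_by_priming_filter(small_bundle):
    """Every decoy context begins with >=6 A on the transcribed strand —
    checked with an independent regex on the generated FASTA."""
    oracle = re.compile(r"^A{6,}")
    from apaseq.model import MappedReadEnd
    for truth in small_bundle.truths:
        read = MappedReadEnd(chrom=truth.chrom,
                             cleavage_pos=truth.decoy_position,
                             strand=truth.strand, sample_id="x",
                             read_length=30, map_score=5.0)
        context = priming_context(read, small_bundle.genome)
        assert oracle.match(context)
        assert is_internal_priming(read, small_bundle.genome)


def test_degenerate_noise_reads_sit_on_true_sites():
    cfg = SimConfig(n_genes=20, cleavage_jitter_sd=0.0,
                    internal_priming_rate=0.0, seed=3)
    bundle = generate_bundle(cfg)
    true_positions = {(t.chrom, p) for t in bundle.truths
                      for p in t.site_positions}
    for reads in bundle.reads.values():
        assert all((r.chrom, r.cleavage_pos) in true_positions for r in reads)


def test_observed_proximal_share_matches_planted_fraction():
    """With proximal fraction 0.8 and ~10,000 reads over 2 sites the observed
    share must fall within a 0.02 binomial-error band."""
    cfg = SimConfig(n_genes=30, sites_per_gene=(2, 2),
                    reads_per_gene_per_sample=350.0, apa_gene_fraction=1.0,
                    proximal_fraction_tumor=0.8, cleavage_jitter_sd=0.0,
                    internal_priming_rate=0.0, seed=5)
    bundle = generate_reference(cfg)
    reads = simulate_sample_reads(bundle, "NE_MTT")
    assert len(reads) > 5000
    proximal = {(t.chrom, t.site_positions[0]) for t in bundle.truths}
    share = np.mean([(r.chrom, r.cleavage_pos) in proximal for r in reads])
    assert share == pytest.approx(0.8, abs=0.02)


def test_same_seed_same_sample_identical_reads():
    cfg = SimConfig(n_genes=10, seed=9)
    bundle = generate_reference(cfg)
    assert simulate_sample_reads(bundle, "PIT") \
        == simulate_sample_reads(bundle, "PIT")
    assert simulate_sample_reads(bundle, "PIT") \
        != simulate_sample_reads(bundle, "NE_CT1")


def test_unknown_sample_raises(small_bundle):
    with pytest.raises(ValueError, match="unknown sample"):
        simulate_sample_reads(small_bundle, "nope")


def test_sites_within_gene_separated_by_at_least_50(small_bundle):
    for t in small_bundle.truths:
        positions = sorted(t.site_positions)
        assert all(b - a >= 50 for a, b in zip(positions, positions[1:]))


def test_usage_fractions_sum_to_one_and_flag_consistency(small_bundle):
    cfg = small_bundle.config
    for t in small_bundle.truths:
        for usage in t.usage.values():
            assert sum(usage) == pytest.approx(1.0)
        tumor_prox = t.usage[cfg.tumor_samples[0]][0]
        ref_prox = t.usage[cfg.reference_sample][0]
        assert t.apa_flag == (tumor_prox != ref_prox)


def test_bundle_round_trip(tmp_path, small_bundle):
    write_fixture_bundle(small_bundle, tmp_path)
    back = read_fixture_bundle(tmp_path)
    assert back.config == small_bundle.config
    assert back.genome == small_bundle.genome
    assert sorted(back.genes, key=lambda g: g.gene_id) \
        == sorted(small_bundle.genes, key=lambda g: g.gene_id)
    assert back.truths == small_bundle.truths
    assert back.reads == small_bundle.reads
    assert sorted(back.mirna_targets, key=lambda t: (t.chrom, t.start, t.mirna_id)) \
        == sorted(small_bundle.mirna_targets, key=lambda t: (t.chrom, t.start, t.mirna_id))
    assert back.expressed_mirnas == small_bundle.expressed_mirnas


def test_resimulation_from_manifest_reproduces_bundle(tmp_path, small_bundle):
    write_fixture_bundle(small_bundle, tmp_path)
    back = read_fixture_bundle(tmp_path)
    fresh = generate_bundle(back.config)
    assert fresh.reads == small_bundle.reads
    assert fresh.genome == small_bundle.genome


def test_missing_directory_is_an_error(tmp_path, small_bundle):
    with pytest.raises(FileNotFoundError):
        write_fixture_bundle(small_bundle, tmp_path / "does_not_exist")
    assert not (tmp_path / "does_not_exist").exists()
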