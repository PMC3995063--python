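"""The five post-hoc selection rules for significant genes."""

import pytest

from apaseq.curation import (apply_read_support_rule, apply_structural_rules,
                             apply_truncation_direction_rules, curate_gene,
                             implicated_sites)
from apaseq.model import GeneSiteTable
from tests.test_annotate import make_gene

TUMORS = ["t1", "t2", "t3"]
REF = "ref"


def table(counts_by_sample, positions=(100, 200), strand="+"):
    return GeneSiteTable(gene_id="geneA", strand=strand,
                         site_positions=list(positions),
                         counts={s: list(c) for s, c in counts_by_sample.items()})


def truncation_pattern(prox_tumor=80, prox_ref=10):
    """Proximal-dominant tumors, distal-dominant reference (the pattern the
    analysis selects for)."""
    return table({"t1": [prox_tumor, 100 - prox_tumor],
                  "t2": [prox_tumor, 100 - prox_tumor],
                  "t3": [prox_tumor, 100 - prox_tumor],
                  "ref": [prox_ref, 100 - prox_ref]})


def test_implicated_sites_are_the_largest_shift_pair():
    t = table({"t1": [70, 20, 10], "t2": [75, 15, 10], "t3": [65, 25, 10],
               "ref": [10, 20, 70]}, positions=(100, 200, 300))
    assert implicated_sites(t, TUMORS, REF) == (0, 2)


# --- rules 1-2 (structure) --------------------------------------------------

GENE = make_gene()  # span 10_000 .. 12_300


def sites_table(positions):
    counts = {s: [80] + [20] * (len(positions) - 1) for s in TUMORS}
    counts["ref"] = [10] + [90] * (len(positions) - 1)
    return table(counts, positions=positions)


def test_sites_inside_own_gene_pass_structural_rules():
    t = sites_table((10_700, 11_700))
    assert apply_structural_rules(t, GENE, [GENE], TUMORS, REF) is None


def test_tandem_transcript_rule():
    # the implicated distal site lies far past the gene's own transcripts:
    # only a tandem/read-through transcript could produce it
    t = sites_table((10_700, 15_000))
    assert apply_structural_rules(t, GENE, [GENE], TUMORS, REF) \
        == "tandem_transcript"


def test_downstream_flank_does_not_fire_tandem_rule():
    t = sites_table((10_700, 12_800))  # 500 nt past the gene end
    assert apply_structural_rules(t, GENE, [GENE], TUMORS, REF) is None


def test_overlapping_gene_rule():
    nested = make_gene("geneB", start=11_500)
    t = sites_table((10_700, 11_700))  # 11_700 is inside geneB's transcript
    assert apply_structural_rules(t, GENE, [GENE, nested], TUMORS, REF) \
        == "overlapping_gene"


def test_antisense_overlap_does_not_fire():
    nested = make_gene("geneB", start=11_500, strand="-")
    t = sites_table((10_700, 11_700))
    assert apply_structural_rules(t, GENE, [GENE, nested], TUMORS, REF) is None


# --- rule 3 (read support) --------------------------------------------------

def support_table(prox, dist):
    counts = {s: [p, d] for s, (p, d) in zip(TUMORS, zip(prox, dist))}
    counts["ref"] = [1, 99]
    return table(counts)


def test_low_support_fires_when_both_sites_weak():
    t = support_table(prox=[9, 8, 50], dist=[3, 2, 40])
    assert apply_read_support_rule(t, TUMORS, REF) == "low_read_support"


def test_one_of_three_below_threshold_is_kept():
    t = support_table(prox=[10, 12, 9], dist=[30, 30, 30])
    assert apply_read_support_rule(t, TUMORS, REF) is None


def test_strong_support_is_kept():
    t = support_table(prox=[100, 100, 100], dist=[50, 50, 50])
    assert apply_read_support_rule(t, TUMORS, REF) is None


def test_any_mode_fires_on_a_single_weak_site():
    t = support_table(prox=[9, 8, 50], dist=[40, 40, 40])
    assert apply_read_support_rule(t, TUMORS, REF, mode="both") is None
    assert apply_read_support_rule(t, TUMORS, REF, mode="any") \
        == "low_read_support"


# --- rules 4-5 (direction) --------------------------------------------------

def test_distal_dominant_in_tumors_is_removed():
    t = table({"t1": [40, 60], "t2": [45, 55], "t3": [30, 70],
               "ref": [40, 60]})
    assert apply_truncation_direction_rules(t, TUMORS, REF) \
        == "distal_dominant_tumor"


def test_proximal_dominant_in_reference_is_removed():
    t = table({"t1": [80, 20], "t2": [80, 20], "t3": [80, 20],
               "ref": [80, 20]})
    assert apply_truncation_direction_rules(t, TUMORS, REF) \
        == "proximal_dominant_reference"


def test_target_truncation_pattern_is_kept():
    assert apply_truncation_direction_rules(truncation_pattern(), TUMORS, REF) \
        is None


def test_plurality_tie_is_conservative():
    t = table({"t1": [50, 50], "t2": [50, 50], "t3": [40, 60],
               "ref": [50, 50]})
    assert apply_truncation_direction_rules(t, TUMORS, REF) is None


# --- combined ---------------------------------------------------------------

def test_first_firing_rule_is_recorded_and_kept_iff_none():
    kept_table = table({"t1": [80, 20], "t2": [80, 20], "t3": [80, 20],
                        "ref": [10, 90]}, positions=(10_700, 11_700))
    decision = curate_gene(kept_table, GENE, [GENE], TUMORS, REF)
    assert decision.rule_fired == "none" and decision.kept

    removed = curate_gene(
        table({"t1": [40, 60], "t2": [45, 55], "t3": [30, 70],
               "ref": [40, 60]}, positions=(10_700, 11_700)),
        GENE, [GENE], TUMORS, REF)
    assert removed.rule_fired == "distal_dominant_tumor" and not removed.kept


def test_planted_proximal_shifts_never_fire_direction_rules(small_bundle,
                                                            small_result):
    """Rules 4-5 target the opposite shift direction; planted tumor-proximal
    genes must never trigger them."""
    planted = {t.gene_id for t in small_bundle.truths if t.apa_flag}
    fired = {g: d.rule_fired for g, d in small_result.decisions.items()
             if g in planted}
    assert fired, "no planted gene was significant"
    assert all(r not in ("distal_dominant_tumor",
                         "proximal_dominant_reference")
               for r in fired.values())
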