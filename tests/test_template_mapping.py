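"""Best-hit mapping, threshold filtering and conflict resolution."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osmonet.errors import ParseError
from osmonet.synthetic_world import true_orthologs
from osmonet.template_mapping import (
    HomologyHit,
    MappedPair,
    MappingThresholds,
    OrganismMapping,
    TemplateEntry,
    TemplateNetwork,
    map_template,
    merge_mappings,
)


def _template(org, genes):
    return TemplateNetwork(org, [TemplateEntry(g, g, f"role of {g}")
                                 for g in genes])


def test_best_evalue_subject_wins():
    t = _template("E_coli", ["q1"])
    hits = [HomologyHit("q1", "t_a", 1e-25, 90.0),
            HomologyHit("q1", "t_b", 1e-30, 120.0)]
    mapping = map_template(t, hits, thr=MappingThresholds())
    assert [(p.template_gene, p.target_gene) for p in mapping.pairs] == \
        [("q1", "t_b")]


def test_sequence_search_hit_above_threshold_is_unmapped():
    t = _template("E_coli", ["q1"])
    hits = [HomologyHit("q1", "t_a", 1e-10, 50.0, "sequence_search")]
    assert map_template(t, hits, thr=MappingThresholds()).pairs == []


def test_orthology_map_channel_uses_its_looser_threshold():
    t = _template("E_coli", ["q1"])
    hits = [HomologyHit("q1", "t_a", 1e-7, 50.0, "orthology_map")]
    mapping = map_template(t, hits, thr=MappingThresholds())
    assert [p.target_gene for p in mapping.pairs] == ["t_a"]


def test_operon_consistency_breaks_equal_evalue_ties():
    t = _template("E_coli", ["q1", "q2"])
    operons = {"t_in": "op1", "t_anchor": "op1", "t_out": "op2"}
    hits = [
        HomologyHit("q1", "t_anchor", 1e-30, 100.0),
        # equal-E tie: lexicographic alone would pick t_aaa
        HomologyHit("q2", "t_aaa", 1e-25, 90.0),
        HomologyHit("q2", "t_in", 1e-25, 90.0),
    ]
    mapping = map_template(t, hits, operons=operons, thr=MappingThresholds())
    chosen = {p.template_gene: p.target_gene for p in mapping.pairs}
    assert chosen["q2"] == "t_in"


def test_malformed_hit_row_names_the_line(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("a\tb\tc\n")
    from osmonet.io import read_blast_tabular
    with pytest.raises(ParseError, match="hits.tsv:1"):
        read_blast_tabular(p)


def test_empty_hit_table_maps_nothing():
    t = _template("E_coli", ["q1"])
    assert map_template(t, [], thr=MappingThresholds()).pairs == []


def test_mapping_recall_on_planted_world(world, thresholds):
    for org in sorted(world.templates):
        mapping = map_template(world.templates[org], world.hits[org],
                               world.operons, thresholds)
        found = {(p.template_gene, p.target_gene) for p in mapping.pairs}
        truth = set(true_orthologs(world, org))
        assert len(found & truth) / len(truth) >= 0.9


def test_closer_relative_wins_shared_target():
    """The trehalose/glucosylglycerol synthase conflict: both OtsA (E. coli)
    and GgpS (PCC6803) hit the same target; the cyanobacterial template is
    the closer relative and its role assignment is kept."""
    thr = MappingThresholds(
        organism_priority=("A_halo", "PCC6803", "P_mari", "C_glut", "E_coli"))
    eco = OrganismMapping(
        "E_coli", [MappedPair("b1896", "SYNW1281", 1e-40)],
        _template("E_coli", ["b1896"]))
    pcc = OrganismMapping(
        "PCC6803", [MappedPair("sll1566", "SYNW1281", 1e-35)],
        _template("PCC6803", ["sll1566"]))
    model = merge_mappings([eco, pcc], thr)
    rec = model.record("SYNW1281")
    assert rec.organism == "PCC6803"
    assert rec.source_gene == "sll1566"


def test_merge_is_idempotent(world, thresholds):
    mappings = [map_template(world.templates[org], world.hits[org],
                             world.operons, thresholds)
                for org in sorted(world.templates)]
    once = merge_mappings(mappings, thresholds)
    twice = merge_mappings(mappings + mappings, thresholds)
    assert once.members == twice.members
    for g in once.members:
        assert once.record(g).source_gene == twice.record(g).source_gene


def test_same_organism_equal_evalue_conflict_warns_and_is_deterministic():
    thr = MappingThresholds()
    m = OrganismMapping(
        "E_coli",
        [MappedPair("q_b", "t_x", 1e-30), MappedPair("q_a", "t_x", 1e-30)],
        _template("E_coli", ["q_a", "q_b"]))
    with pytest.warns(UserWarning, match="unresolved conflict"):
        model = merge_mappings([m], thr)
    assert model.record("t_x").source_gene == "q_a"  # lexicographic winner
    assert model.warnings


def test_three_way_conflicts_resolved_by_priority_for_all_orders():
    orgs = ("A_halo", "PCC6803", "E_coli")
    for priority in itertools.permutations(orgs):
        thr = MappingThresholds(organism_priority=priority)
        mappings = [
            OrganismMapping(org, [MappedPair(f"{org}_q", "t_x", 1e-30)],
                            _template(org, [f"{org}_q"]))
            for org in orgs
        ]
        model = merge_mappings(mappings, thr)
        assert model.record("t_x").organism == priority[0]


def test_single_organism_without_conflicts_keeps_all_pairs():
    m = OrganismMapping(
        "E_coli",
        [MappedPair("q1", "t1", 1e-30), MappedPair("q2", "t2", 1e-25)],
        _template("E_coli", ["q1", "q2"]))
    model = merge_mappings([m], MappingThresholds())
    assert len(model) == 2
    assert model.record("t1").role == "role of q1"


@settings(max_examples=50, deadline=None)
@given(st.lists(
    st.tuples(st.sampled_from(["q1", "q2", "q3"]),
              st.sampled_from(["t1", "t2", "t3", "t4"]),
              st.floats(min_value=1e-60, max_value=1e-5),
              st.sampled_from(["orthology_map", "sequence_search"])),
    max_size=20),
    st.floats(min_value=1e-40, max_value=1e-10))
def test_tightening_thresholds_never_adds_pairs(rows, tighter_seq):
    """Monotonicity: every pair mapped under a stricter E-value cutoff is
    also mapped under the looser default cutoffs."""
    t = _template("E_coli", ["q1", "q2", "q3"])
    hits = [HomologyHit(q, s, e, 50.0, tool) for q, s, e, tool in rows]
    loose = map_template(t, hits, thr=MappingThresholds())
    tight_thr = MappingThresholds(
        orthology_map_evalue_max=min(1e-6, tighter_seq * 10),
        sequence_search_evalue_max=min(1e-20, tighter_seq))
    tight = map_template(t, hits, thr=tight_thr)
    assert {p.template_gene for p in tight.pairs} <= \
        {p.template_gene for p in loose.pairs}
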