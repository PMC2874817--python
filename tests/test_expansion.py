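"""Operon / PPI / regulon recruitment and evidence merging."""

import pytest

from osmonet.errors import DataError
from osmonet.expansion import (
    OperonTable,
    PPIList,
    Recruit,
    RegulonDefinition,
    map_regulon,
    merge_evidence,
    recruit_by_operon,
    recruit_by_ppi,
)
from osmonet.template_mapping import (
    GeneRecord,
    HomologyHit,
    MappingThresholds,
    NetworkModel,
)


def _model_of(genes):
    m = NetworkModel()
    for g in genes:
        m.add(GeneRecord(gene=g, source_gene="src", evidence={"template"}))
    return m


def test_operon_mates_of_model_genes_are_recruited():
    operons = OperonTable({"op1": ["g1", "g2", "g3"], "op2": ["g4", "g5"]})
    recruits = recruit_by_operon(_model_of(["g1"]), operons)
    assert {(r.gene, r.anchor) for r in recruits} == \
        {("g2", "op1"), ("g3", "op1")}


def test_model_gene_outside_any_operon_recruits_nothing():
    operons = OperonTable({"op1": ["g4", "g5"]})
    assert recruit_by_operon(_model_of(["g1"]), operons) == []


def test_gene_in_two_operons_is_a_data_error():
    with pytest.raises(DataError, match="g2"):
        OperonTable({"op1": ["g1", "g2"], "op2": ["g2", "g3"]})


def test_ppi_neighbours_recruited_with_partner_recorded():
    ppi = PPIList([("m", "x"), ("x", "y")])
    recruits = recruit_by_ppi(_model_of(["m"]), ppi)
    assert [(r.gene, r.anchor) for r in recruits] == [("x", "m")]


def test_ppi_edge_between_non_model_genes_recruits_nothing():
    ppi = PPIList([("x", "y")])
    assert recruit_by_ppi(_model_of(["m"]), ppi) == []


def test_star_graph_recruits_every_leaf():
    leaves = [f"leaf{i}" for i in range(6)]
    ppi = PPIList([("hub", leaf) for leaf in leaves])
    recruits = recruit_by_ppi(_model_of(["hub"]), ppi)
    assert sorted(r.gene for r in recruits) == sorted(leaves)
    assert all(r.anchor == "hub" for r in recruits)


def test_self_edge_rejected_and_duplicates_collapsed():
    with pytest.raises(DataError):
        PPIList([("a", "a")])
    assert len(PPIList([("a", "b"), ("b", "a"), ("a", "b")])) == 1


def test_regulon_mapping_recovers_exactly_the_planted_orthologs(world,
                                                                thresholds):
    recruits = map_regulon(world.regulon, world.regulon_hits, thresholds)
    assert {(r.anchor, r.gene) for r in recruits} == \
        set(world.regulon_true_targets.items())
    assert len(recruits) == world.config.n_regulon_orthologs


def test_empty_regulon_maps_to_nothing(thresholds):
    reg = RegulonDefinition("sigma38", "E_coli", [])
    assert map_regulon(reg, [], thresholds) == []


def test_regulon_members_already_in_model_are_corroborated_not_duplicated(
        world, initial_model, thresholds):
    recruits = map_regulon(world.regulon, world.regulon_hits, thresholds)
    already = {r.gene for r in recruits} & initial_model.members
    assert already  # the generator plants a few corroborating targets
    model, report = merge_evidence(initial_model, {"regulon": recruits})
    assert report.channel_corroborated["regulon"] == len(already)
    assert report.channel_new["regulon"] == len(recruits) - len(already)
    for g in already:
        assert model.record(g).evidence >= {"template", "regulon"}


def test_merge_accumulates_tags_and_unions_channels():
    initial = _model_of(["m"])
    channels = {
        "operon": [Recruit("a", "operon", "op1"), Recruit("b", "operon", "op1")],
        "ppi": [Recruit("b", "ppi", "m"), Recruit("c", "ppi", "m")],
    }
    model, report = merge_evidence(initial, channels)
    assert model.members == {"m", "a", "b", "c"}
    assert model.record("b").evidence == {"operon", "ppi"}
    assert report.n_new_union == 3
    assert report.channel_new == {"operon": 2, "ppi": 2}


def test_merging_empty_channels_is_identity(world, initial_model):
    model, report = merge_evidence(initial_model, {})
    assert model.members == initial_model.members
    assert report.n_new_union == 0


def test_union_arithmetic_with_planted_overlaps():
    """Channel sizes 24/15/41/13 with 7 genes shared between the first two
    channels must union to 86 new genes, mirroring multi-channel overlap
    bookkeeping."""
    initial = _model_of(["m"])
    operon = [Recruit(f"o{i}", "operon", "op") for i in range(24)]
    ppi = [Recruit(f"o{i}", "ppi", "m") for i in range(7)] + \
        [Recruit(f"p{i}", "ppi", "m") for i in range(8)]
    regulon = [Recruit(f"r{i}", "regulon", "reg") for i in range(41)]
    profile = [Recruit(f"f{i}", "profile", "m") for i in range(13)]
    model, report = merge_evidence(
        initial, {"operon": operon, "ppi": ppi, "regulon": regulon,
                  "profile": profile})
    assert report.channel_new == \
        {"operon": 24, "ppi": 15, "regulon": 41, "profile": 13}
    assert report.n_new_union == 86
    assert report.n_expanded == 87


def test_expansion_is_monotone_and_bounded(world, initial_model, expanded):
    model, report = expanded
    assert initial_model.members <= model.members
    assert report.n_new_union <= sum(report.channel_new.values())
    for rec in model.records():
        assert rec.evidence  # every member carries at least one tag
        if rec.gene not in initial_model.members:
            assert rec.anchors  # provenance chain recorded for recruits


def test_recruit_channel_mismatch_is_rejected():
    with pytest.raises(DataError):
        merge_evidence(_model_of(["m"]),
                       {"operon": [Recruit("x", "ppi", "m")]})
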