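import pytest

from osmonet.expansion import (
    Recruit,
    map_regulon,
    merge_evidence,
    recruit_by_operon,
    recruit_by_ppi,
)
from osmonet.phylo_profiles import recruit_by_profile
from osmonet.synthetic_world import build_world, scaled_down_config
from osmonet.template_mapping import (
    MappingThresholds,
    map_template,
    merge_mappings,
)

WORLD_SEED = 11


@pytest.fixture(scope="session")
def thresholds():
    return MappingThresholds()


@pytest.fixture(scope="session")
def world():
    """One desk-scale synthetic world shared by read-only tests."""
    return build_world(scaled_down_config(seed=WORLD_SEED))


@pytest.fixture(scope="session")
def initial_model(world, thresholds):
    mappings = [
        map_template(world.templates[org], world.hits[org], world.operons,
                     thresholds)
        for org in sorted(world.templates)
    ]
    return merge_mappings(mappings, thresholds)


@pytest.fixture(scope="session")
def expanded(world, initial_model, thresholds):
    channels = {
        "operon": recruit_by_operon(initial_model, world.operons),
        "ppi": recruit_by_ppi(initial_model, world.ppi),
        "regulon": map_regulon(world.regulon, world.regulon_hits, thresholds),
    }
    rec = recruit_by_profile(initial_model, world.presence)
    channels["profile"] = [Recruit(r.gene, "profile", r.anchor, r.score)
                           for r in rec.recruits]
    return merge_evidence(initial_model, channels)
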