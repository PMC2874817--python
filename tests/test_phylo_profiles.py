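"""Profile likelihood, relatedness measure and co-evolution recruitment."""

import math

import numpy as np
import pandas as pd
import pytest

from osmonet.errors import DimensionError
from osmonet.phylo_profiles import (
    PanelMarginals,
    PhyloProfile,
    ProfileRecruitment,
    RelatednessParams,
    phylo_relatedness,
    profile_likelihood,
    recruit_by_profile,
    relatedness_matrix,
)
from osmonet.template_mapping import GeneRecord, NetworkModel


def test_likelihood_of_all_ones_profile_at_half_frequency():
    # every genome carries half the target genes -> p_j = 0.5 everywhere
    marg = PanelMarginals(n=4, m=np.array([50, 50, 50, 50]), n_genes=100)
    p = PhyloProfile("g", np.ones(4))
    assert profile_likelihood(p, marg) == pytest.approx(4 * math.log(0.5))


def test_ubiquitous_gene_in_saturated_panel_has_maximal_likelihood():
    rng = np.random.default_rng(0)
    marg = PanelMarginals(n=6, m=np.full(6, 100), n_genes=100)  # clamped
    full = profile_likelihood(PhyloProfile("g", np.ones(6)), marg)
    for _ in range(50):
        other = PhyloProfile("x", rng.integers(0, 2, 6))
        assert profile_likelihood(other, marg) <= full + 1e-12


def test_likelihood_matches_independent_product_formula():
    rng = np.random.default_rng(42)
    mat = rng.integers(0, 2, (10, 6))
    marg = PanelMarginals(n=6, m=mat.sum(axis=0), n_genes=10)
    eps = 1 / 20
    for i in range(10):
        expected = 1.0
        for j in range(6):
            pj = min(max(mat[:, j].sum() / 10, eps), 1 - eps)
            expected *= pj if mat[i, j] == 1 else 1 - pj
        got = profile_likelihood(PhyloProfile(f"g{i}", mat[i]), marg)
        assert got == pytest.approx(math.log(expected))


def test_profile_length_mismatch_raises():
    marg = PanelMarginals(n=4, m=np.array([1, 2, 3, 1]), n_genes=10)
    with pytest.raises(DimensionError):
        profile_likelihood(PhyloProfile("g", np.ones(5)), marg)
    with pytest.raises(DimensionError):
        phylo_relatedness(PhyloProfile("a", np.ones(3)),
                          PhyloProfile("b", np.ones(4)))


def test_relatedness_symmetry_on_random_pairs():
    rng = np.random.default_rng(1)
    for _ in range(100):
        a = PhyloProfile("a", rng.integers(0, 2, 30))
        b = PhyloProfile("b", rng.integers(0, 2, 30))
        assert phylo_relatedness(a, b) == pytest.approx(phylo_relatedness(b, a))


def test_identical_profiles_beat_any_single_flip():
    rng = np.random.default_rng(2)
    bits = rng.integers(0, 2, 20)
    a = PhyloProfile("a", bits)
    base = phylo_relatedness(a, PhyloProfile("b", bits.copy()))
    for j in range(20):
        flipped = bits.copy()
        flipped[j] ^= 1
        assert phylo_relatedness(a, PhyloProfile("b", flipped)) < base


def test_score_decreasing_in_hamming_and_nondecreasing_in_overlap():
    # fixed h, growing d_H: append disagreeing positions
    a = PhyloProfile("a", [1, 1, 1, 0, 0, 1, 0])
    b1 = PhyloProfile("b", [1, 1, 1, 0, 0, 0, 0])  # d_H=1, h=3
    b2 = PhyloProfile("b", [1, 1, 1, 1, 0, 0, 0])  # d_H=2, h=3
    assert phylo_relatedness(a, b1) > phylo_relatedness(a, b2)
    # fixed d_H, growing h
    a2 = PhyloProfile("a", [1, 1, 0, 0, 1, 0, 0])
    c1 = PhyloProfile("c", [1, 1, 0, 0, 0, 0, 0])  # h=2, d_H=1
    a3 = PhyloProfile("a", [1, 1, 1, 0, 1, 0, 0])
    c2 = PhyloProfile("c", [1, 1, 1, 0, 0, 0, 0])  # h=3, d_H=1
    assert phylo_relatedness(a3, c2) >= phylo_relatedness(a2, c1)


def test_pairwise_ranking_matches_bruteforce_oracle():
    """The vectorised relatedness matrix must rank all gene pairs exactly
    as a direct per-pair evaluation of the closed form does."""
    rng = np.random.default_rng(3)
    mat = rng.integers(0, 2, (20, 15))
    fast = relatedness_matrix(mat, mat)
    genes = [PhyloProfile(f"g{i}", mat[i]) for i in range(20)]
    slow = np.zeros((20, 20))
    for i in range(20):
        for j in range(20):
            d = sum(int(x != y) for x, y in zip(mat[i], mat[j]))
            h = sum(int(x == 1 and y == 1) for x, y in zip(mat[i], mat[j]))
            slow[i, j] = (h + 1) / (1 + d) ** 2
    assert np.allclose(fast, slow)
    for i in range(20):
        assert phylo_relatedness(genes[i], genes[(i + 7) % 20]) == \
            pytest.approx(slow[i, (i + 7) % 20])


def test_panel_permutation_invariance():
    rng = np.random.default_rng(4)
    a = rng.integers(0, 2, 25)
    b = rng.integers(0, 2, 25)
    perm = rng.permutation(25)
    s1 = phylo_relatedness(PhyloProfile("a", a), PhyloProfile("b", b))
    s2 = phylo_relatedness(PhyloProfile("a", a[perm]),
                           PhyloProfile("b", b[perm]))
    assert s1 == pytest.approx(s2)


def test_genome_where_both_absent_leaves_score_unchanged():
    a = np.array([1, 0, 1, 1, 0])
    b = np.array([1, 1, 1, 0, 0])
    s1 = phylo_relatedness(PhyloProfile("a", a), PhyloProfile("b", b))
    s2 = phylo_relatedness(PhyloProfile("a", np.append(a, 0)),
                           PhyloProfile("b", np.append(b, 0)))
    assert s1 == pytest.approx(s2)


def _model_of(genes):
    m = NetworkModel()
    for g in genes:
        m.add(GeneRecord(gene=g, source_gene="src", evidence={"template"}))
    return m


def test_single_gene_model_recruits_nothing():
    profiles = pd.DataFrame(np.eye(3, dtype=int),
                            index=["g0", "g1", "g2"])
    out = recruit_by_profile(_model_of(["g0"]), profiles)
    assert isinstance(out, ProfileRecruitment)
    assert out.recruits == []


def test_model_gene_without_profile_is_skipped_not_fatal():
    rng = np.random.default_rng(5)
    profiles = pd.DataFrame(rng.integers(0, 2, (5, 8)),
                            index=[f"g{i}" for i in range(5)])
    out = recruit_by_profile(_model_of(["g0", "g1", "missing"]), profiles)
    assert out.skipped_model_genes == ["missing"]


def test_recruits_share_their_anchors_planted_module(world, initial_model):
    out = recruit_by_profile(initial_model, world.presence)
    assert len(out.recruits) >= 5
    by_gene = {}
    for r in out.recruits:
        by_gene.setdefault(r.gene, []).append(r.anchor)
    pure = sum(
        1 for g, anchors in by_gene.items()
        if any(world.gene_module.get(g) is not None
               and world.gene_module.get(g) == world.gene_module.get(a)
               for a in anchors))
    assert pure / len(by_gene) >= 0.7


def test_recruitment_output_is_deterministically_sorted(world, initial_model):
    out1 = recruit_by_profile(initial_model, world.presence)
    out2 = recruit_by_profile(initial_model, world.presence)
    assert out1.recruits == out2.recruits
    assert out1.recruits == sorted(out1.recruits,
                                   key=lambda r: (r.gene, r.anchor))


def test_recruit_beats_every_competing_model_gene(world, initial_model):
    """Spot-check the recruitment rule: each recruit's score to its anchor
    exceeds the best score any other model gene achieves with that anchor."""
    out = recruit_by_profile(initial_model, world.presence)
    bits = world.presence.to_numpy()
    idx = {g: i for i, g in enumerate(world.presence.index)}
    model_genes = sorted(initial_model.members)
    for r in out.recruits[:10]:
        anchor_bits = bits[[idx[r.anchor]]]
        others = [g for g in model_genes if g != r.anchor]
        bar = relatedness_matrix(
            bits[[idx[g] for g in others]], anchor_bits).max()
        assert r.score > bar


def test_alpha_must_be_positive():
    with pytest.raises(Exception):
        RelatednessParams(alpha=0.0)
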