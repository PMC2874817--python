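"""DE calling, hypergeometric tails and pathway enrichment."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from osmonet.errors import DataError
from osmonet.validation_stats import (
    DECallParams,
    HypergeomInputs,
    call_de,
    hypergeom_tail,
    pathway_enrichment,
    report_from_counts,
    validate_channels,
)


@pytest.mark.parametrize("fc, label", [
    (2.0, "up"), (0.5, "down"), (1.0, "none"),
    (2.5, "up"), (0.3, "down"), (1.99, "none"), (0.51, "none"),
])
def test_de_boundaries_are_inclusive(fc, label):
    assert call_de({"g": fc})["g"] == label


def test_de_labels_match_direct_threshold_enumeration():
    rng = np.random.default_rng(0)
    fc = {f"g{i}": float(v) for i, v in
          enumerate(np.exp(rng.normal(0, 0.8, 500)))}
    calls = call_de(fc)
    for g, v in fc.items():
        expected = "up" if v >= 2.0 else ("down" if v <= 0.5 else "none")
        assert calls[g] == expected


def test_nonpositive_fold_change_rejected():
    with pytest.raises(DataError):
        call_de({"g": 0.0})
    with pytest.raises(Exception):
        DECallParams(up_cutoff=0.9)


def _exact_tail(N, A, K, V) -> Fraction:
    total = Fraction(0)
    for i in range(V, min(A, K) + 1):
        total += Fraction(math.comb(A, i) * math.comb(N - A, K - i),
                          math.comb(N, K))
    return total


def test_zero_observed_gives_probability_one():
    assert hypergeom_tail(HypergeomInputs(100, 10, 5, 0)) == 1.0


def test_published_style_tail_value():
    # a weak single-overlap channel: K=16 draws, V=1 of A=102 in N=2520
    p = hypergeom_tail(HypergeomInputs(2520, 102, 16, 1))
    assert f"{p:.2g}" == "0.48"


def test_small_case_matches_exhaustive_draw_enumeration():
    # enumerate all C(10,4) draws directly
    N, A, K, V = 10, 3, 4, 2
    successes = set(range(A))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), K):
        total += 1
        if len(successes & set(draw)) >= V:
            hits += 1
    assert hypergeom_tail(HypergeomInputs(N, A, K, V)) == \
        pytest.approx(hits / total)


def test_tail_matches_exact_rational_arithmetic_up_to_n50():
    rng = np.random.default_rng(1)
    for _ in range(80):
        N = int(rng.integers(2, 51))
        A = int(rng.integers(0, N + 1))
        K = int(rng.integers(0, N + 1))
        V = int(rng.integers(0, min(A, K) + 1))
        exact = float(_exact_tail(N, A, K, V))
        assert hypergeom_tail(HypergeomInputs(N, A, K, V)) == \
            pytest.approx(exact, rel=1e-10, abs=1e-300)


def test_tail_is_nonincreasing_in_observed_count():
    N, A, K = 200, 30, 25
    ps = [hypergeom_tail(HypergeomInputs(N, A, K, v))
          for v in range(min(A, K) + 1)]
    assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


def test_pmf_sums_to_one_at_small_n():
    N, A, K = 12, 5, 7
    total = sum(
        Fraction(math.comb(A, i) * math.comb(N - A, K - i), math.comb(N, K))
        for i in range(max(0, K - (N - A)), min(A, K) + 1))
    assert total == 1


def test_invalid_inputs_rejected():
    with pytest.raises(DataError):
        HypergeomInputs(10, 3, 4, 5)  # V > min(A, K)
    with pytest.raises(DataError):
        HypergeomInputs(10, 11, 4, 0)


def test_channel_report_shares_one_population(world, expanded):
    model, _ = expanded
    calls = call_de(world.expression)
    report = validate_channels(model, calls, N=len(world.genes))
    assert {r.channel for r in report.rows} == \
        {"initial", "operon", "ppi", "regulon", "profile", "expanded"}
    assert report.A == len(world.de_genes)
    # expanded row covers the whole model; channel rows only recruits
    assert report.row("expanded").K == len(model)
    assert report.row("initial").K == \
        len(model.genes_with_evidence("template"))


def test_report_with_no_de_genes_is_all_ones(world, expanded):
    model, _ = expanded
    calls = {g: "none" for g in world.genes}
    report = validate_channels(model, calls, N=len(world.genes))
    assert all(r.p_value == 1.0 and r.V == 0 for r in report.rows)


def test_report_from_printed_counts():
    rows = [("initial", 27, 9), ("expanded", 114, 15)]
    report = report_from_counts(rows, N=2520, A=102)
    assert f"{report.row('initial').p_value:.3g}" == "5.24e-07"
    assert f"{report.row('expanded').p_value:.3g}" == "3.44e-05"


def test_model_covering_a_whole_small_pathway_is_top_ranked():
    genes = [f"g{i}" for i in range(200)]
    ann = pd.DataFrame(
        [(f"g{i}", "pwA") for i in range(5)]
        + [(f"g{i}", "pwB") for i in range(100, 180)],
        columns=["gene", "pathway"])
    enr = pathway_enrichment([f"g{i}" for i in range(5)], ann, genes)
    assert enr.iloc[0]["pathway"] == "pwA"
    assert enr.iloc[0]["enriched"]


def test_pathway_disjoint_from_model_has_p_one():
    genes = [f"g{i}" for i in range(50)]
    ann = pd.DataFrame([(f"g{i}", "pwA") for i in range(10, 20)],
                       columns=["gene", "pathway"])
    enr = pathway_enrichment(["g0", "g1"], ann, genes)
    row = enr[enr["pathway"] == "pwA"].iloc[0]
    assert row["V"] == 0 and row["p_value"] == 1.0


def test_empty_annotation_yields_empty_result():
    enr = pathway_enrichment(["g0"], pd.DataFrame(columns=["gene", "pathway"]),
                             ["g0", "g1"])
    assert enr.empty


def test_planted_pathway_ranks_first(world, expanded):
    model, _ = expanded
    enr = pathway_enrichment(model.members, world.pathway_annotation,
                             world.genes)
    assert enr.iloc[0]["pathway"] == world.planted_pathway
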