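"""Differential-expression calling and hypergeometric validation.

A gene is called up-regulated at fold change >= 2.0, down-regulated at
<= 0.5, unchanged in between (cutoff values themselves count as
differentially expressed; the cutoffs are configurable). Each evidence
channel of the network model is then scored with the inclusive upper-tail
hypergeometric probability

    P = sum_{i=V}^{min(A,K)} C(A,i) C(N-A,K-i) / C(N,K)

of drawing at least V differentially expressed genes in K draws without
replacement from a genome of N genes containing A differentially expressed
ones. The same test, with a pathway as the success class, gives per-pathway
enrichment of the model against the whole-genome background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from osmonet.errors import ConfigurationError, DataError
from osmonet.template_mapping import NetworkModel


@dataclass
class DECallParams:
    """Fold-change cutoffs for calling differential expression."""

    up_cutoff: float = 2.0
    down_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not self.down_cutoff < 1.0 < self.up_cutoff:
            raise ConfigurationError(
                "need down_cutoff < 1 < up_cutoff, got "
                f"{self.down_cutoff} / {self.up_cutoff}")


def call_de(expr: Mapping[str, float] | pd.Series,
            params: DECallParams | None = None) -> dict[str, str]:
    """Label every gene up / down / none from its mean fold change."""
    params = params or DECallParams()
    if isinstance(expr, pd.Series):
        expr = expr.to_dict()
    calls: dict[str, str] = {}
    for gene, fc in expr.items():
        fc = float(fc)
        if not fc > 0 or not np.isfinite(fc):
            raise DataError(f"non-positive fold change for {gene}: {fc}")
        if fc >= params.up_cutoff:
            calls[gene] = "up"
        elif fc <= params.down_cutoff:
            calls[gene] = "down"
        else:
            calls[gene] = "none"
    return calls


@dataclass(frozen=True)
class HypergeomInputs:
    """(N, A, K, V): genome size, successes, draws, observed successes."""

    N: int
    A: int
    K: int
    V: int

    def __post_init__(self) -> None:
        if min(self.N, self.A, self.K, self.V) < 0:
            raise DataError("hypergeometric inputs must be non-negative")
        if self.A > self.N or self.K > self.N:
            raise DataError(f"A={self.A}, K={self.K} cannot exceed N={self.N}")
        if self.V > min(self.A, self.K):
            raise DataError(
                f"V={self.V} exceeds min(A={self.A}, K={self.K})")


def hypergeom_tail(h: HypergeomInputs) -> float:
    """Inclusive upper-tail probability P(X >= V)."""
    if h.V == 0:
        return 1.0
    return float(hypergeom.sf(h.V - 1, h.N, h.A, h.K))


@dataclass
class ChannelRow:
    channel: str
    K: int
    V: int
    p_value: float


@dataclass
class ValidationReport:
    """Per-channel gene counts, DE counts and tail probabilities."""

    N: int
    A: int
    rows: list[ChannelRow] = field(default_factory=list)

    def row(self, channel: str) -> ChannelRow:
        for r in self.rows:
            if r.channel == channel:
                return r
        raise KeyError(channel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"channel": r.channel, "K": r.K, "V": r.V,
              "p_value": f"{r.p_value:.3g}"} for r in self.rows],
            columns=["channel", "K", "V", "p_value"])


#: Report rows, in presentation order, and how each selects model genes.
CHANNEL_ORDER = ("initial", "operon", "ppi", "regulon", "profile", "expanded")


def _channel_genes(model: NetworkModel, channel: str) -> set[str]:
    if channel == "initial":
        return model.genes_with_evidence("template")
    if channel == "expanded":
        return model.members
    # recruited-only rows: genes added by the channel, i.e. carrying the
    # channel tag without a template assignment
    return model.genes_with_evidence(channel) - model.genes_with_evidence("template")


def validate_channels(
    model: NetworkModel,
    de_calls: Mapping[str, str],
    N: int,
    A: int | None = None,
) -> ValidationReport:
    """Hypergeometric validation of every evidence channel and the full model.

    ``de_calls`` maps genome genes to up/down/none labels (or any mapping
    whose truthy labels other than 'none' mark differential expression).
    ``A`` defaults to the number of DE genes among the calls; passing it
    explicitly supports externally produced DE gene lists.
    """
    de_genes = {g for g, lab in de_calls.items() if lab not in ("none", "", None)}
    if A is None:
        A = len(de_genes)
    report = ValidationReport(N=N, A=A)
    for channel in CHANNEL_ORDER:
        genes = _channel_genes(model, channel)
        K = len(genes)
        V = len(genes & de_genes)
        p = hypergeom_tail(HypergeomInputs(N=N, A=A, K=K, V=V))
        report.rows.append(ChannelRow(channel, K, V, p))
    return report


def report_from_counts(rows: Iterable[tuple[str, int, int]],
                       N: int, A: int) -> ValidationReport:
    """Build a validation report directly from printed (channel, K, V) counts."""
    report = ValidationReport(N=N, A=A)
    for channel, K, V in rows:
        p = hypergeom_tail(HypergeomInputs(N=N, A=A, K=K, V=V))
        report.rows.append(ChannelRow(channel, K, V, p))
    return report


def pathway_enrichment(
    model_genes: Iterable[str],
    annotation: pd.DataFrame,
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pathway hypergeometric enrichment of the model vs the genome.

    ``annotation`` has columns (gene, pathway); ``background`` is the full
    gene universe (N). For each pathway: A = pathway size, K = model genes
    with any pathway annotation, V = model genes in the pathway. Pathways
    with raw P <= ``alpha`` are flagged as enriched; a Benjamini-Hochberg
    column is reported alongside but does not drive the flag.
    """
    if not {"gene", "pathway"} <= set(annotation.columns):
        raise DataError("annotation needs columns 'gene' and 'pathway'")
    background = set(background)
    model_genes = set(model_genes) & background
    ann = annotation[annotation["gene"].isin(background)]
    if ann.empty:
        return pd.DataFrame(columns=["pathway", "A", "K", "V", "p_value",
                                     "bh_adjusted", "enriched"])
    annotated = set(ann["gene"])
    K = len(model_genes & annotated)
    N = len(background)
    rows = []
    for pathway, sub in ann.groupby("pathway", sort=True):
        members = set(sub["gene"])
        A = len(members)
        V = len(members & model_genes)
        p = hypergeom_tail(HypergeomInputs(N=N, A=A, K=K, V=V))
        rows.append({"pathway": pathway, "A": A, "K": K, "V": V, "p_value": p})
    df = pd.DataFrame(rows).sort_values(
        ["p_value", "pathway"], kind="stable").reset_index(drop=True)
    df["bh_adjusted"] = false_discovery_control(df["p_value"].to_numpy(),
                                                method="bh")
    df["enriched"] = df["p_value"] <= alpha
    return df
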