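"""Guilt-by-association expansion of the initial network model.

Three of the four recruitment channels live here — operon co-membership,
protein-protein interaction adjacency, and regulon orthology transfer —
plus the merge that unions all channels (including profile-based
recruitment from :mod:`osmonet.phylo_profiles`) into the expanded model.
Expansion is single-pass: recruits do not themselves recruit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from osmonet.errors import DataError
from osmonet.template_mapping import (
    GeneRecord,
    HomologyHit,
    MappedPair,
    MappingThresholds,
    NetworkModel,
    TemplateEntry,
    TemplateNetwork,
    map_template,
)


class OperonTable:
    """operon id -> ordered gene list; a gene belongs to at most one operon."""

    def __init__(self, operons: dict[str, list[str]]):
        self.operons = {k: list(v) for k, v in operons.items()}
        self.gene_to_operon: dict[str, str] = {}
        for op_id, genes in self.operons.items():
            for g in genes:
                if g in self.gene_to_operon and self.gene_to_operon[g] != op_id:
                    raise DataError(
                        f"gene {g} appears in operons "
                        f"{self.gene_to_operon[g]} and {op_id}")
                self.gene_to_operon[g] = op_id

    def __len__(self) -> int:
        return len(self.operons)

    def members(self, op_id: str) -> list[str]:
        return self.operons[op_id]


class PPIList:
    """Deduplicated undirected interaction pairs without self-edges."""

    def __init__(self, edges):
        seen: set[frozenset] = set()
        self.edges: list[tuple[str, str]] = []
        self.neighbors: dict[str, set[str]] = {}
        for u, v in edges:
            if u == v:
                raise DataError(f"self-interaction {u}-{v}")
            key = frozenset((u, v))
            if key in seen:
                continue
            seen.add(key)
            a, b = sorted((u, v))
            self.edges.append((a, b))
            self.neighbors.setdefault(a, set()).add(b)
            self.neighbors.setdefault(b, set()).add(a)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class RegulonDefinition:
    """Member genes of one regulator's regulon in a template organism."""

    regulator: str
    organism: str
    members: list[str]

    def __post_init__(self) -> None:
        if len(self.members) != len(set(self.members)):
            raise DataError(f"duplicate members in regulon {self.regulator}")


@dataclass(frozen=True)
class Recruit:
    """One recruited gene with its provenance anchor."""

    gene: str
    channel: str  # operon | ppi | regulon | profile
    anchor: str   # operon id / interacting partner / source regulon gene / anchor gene
    score: float | None = None


def recruit_by_operon(model: NetworkModel, operons: OperonTable) -> list[Recruit]:
    """Recruit every non-model gene sharing an operon with a model gene."""
    recruits: list[Recruit] = []
    model_operons = sorted({
        operons.gene_to_operon[g] for g in model.members
        if g in operons.gene_to_operon
    })
    for op_id in model_operons:
        for g in operons.members(op_id):
            if g not in model:
                recruits.append(Recruit(g, "operon", op_id))
    recruits.sort(key=lambda r: (r.gene, r.anchor))
    return recruits


def recruit_by_ppi(model: NetworkModel, ppi: PPIList) -> list[Recruit]:
    """Recruit non-model genes adjacent to a model gene, partner recorded."""
    recruits: list[Recruit] = []
    for m in sorted(model.members):
        for g in sorted(ppi.neighbors.get(m, ())):
            if g not in model:
                recruits.append(Recruit(g, "ppi", m))
    recruits.sort(key=lambda r: (r.gene, r.anchor))
    return recruits


def map_regulon(
    reg: RegulonDefinition,
    hits: list[HomologyHit],
    thr: MappingThresholds | None = None,
) -> list[Recruit]:
    """Transfer a template-organism regulon to the target genome.

    Each member is mapped through the same best-hit-above-threshold
    machinery used for template networks; members without a passing hit
    are dropped. Output covers every mapped member, including genes that
    turn out to already sit in the model — the merge step reports those as
    corroborated rather than duplicating them.
    """
    thr = thr or MappingThresholds()
    pseudo = TemplateNetwork(
        reg.organism,
        [TemplateEntry(m, m, f"{reg.regulator} regulon member")
         for m in reg.members],
    )
    mapping = map_template(pseudo, hits, operons=None, thr=thr)
    out = [Recruit(p.target_gene, "regulon", p.template_gene, p.e_value)
           for p in mapping.pairs]
    out.sort(key=lambda r: (r.gene, r.anchor))
    return out


@dataclass
class ExpansionReport:
    """Per-channel recruitment bookkeeping for the expanded model."""

    channel_new: dict[str, int] = field(default_factory=dict)
    channel_corroborated: dict[str, int] = field(default_factory=dict)
    n_initial: int = 0
    n_new_union: int = 0
    n_expanded: int = 0
    notes: list[str] = field(default_factory=list)


def merge_evidence(
    initial: NetworkModel,
    channels: dict[str, list[Recruit]],
) -> tuple[NetworkModel, ExpansionReport]:
    """Union the initial model with all recruitment channels.

    Evidence tags accumulate per gene; a gene recruited by several
    channels enters the union once but is counted in every channel's row.
    Recruits that already belong to the initial model are corroborations:
    they gain the channel tag but do not count as new genes.
    """
    model = initial.copy()
    report = ExpansionReport(n_initial=len(initial))
    new_union: set[str] = set()
    for channel in sorted(channels):
        recruits = channels[channel]
        new_genes: set[str] = set()
        corroborated: set[str] = set()
        for r in recruits:
            if r.channel != channel:
                raise DataError(
                    f"recruit {r.gene} tagged {r.channel!r} in channel "
                    f"{channel!r}")
            if r.gene in initial:
                corroborated.add(r.gene)
                model.record(r.gene).evidence.add(channel)
                model.record(r.gene).anchors.setdefault(channel, r.anchor)
            else:
                new_genes.add(r.gene)
                model.add(GeneRecord(
                    gene=r.gene, evidence={channel},
                    anchors={channel: r.anchor},
                ))
        report.channel_new[channel] = len(new_genes)
        report.channel_corroborated[channel] = len(corroborated)
        new_union |= new_genes
    report.n_new_union = len(new_union)
    report.n_expanded = len(model)
    if report.n_new_union < sum(report.channel_new.values()):
        report.notes.append(
            "channels overlap: union of new genes smaller than channel sum")
    return model, report
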