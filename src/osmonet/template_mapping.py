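"""Initial network construction by template-network orthology mapping.

Curated template networks (gene/role lists from well-studied organisms) are
mapped onto the target genome through homology hits filtered at
tool-specific E-value thresholds (orthology mapper 1e-6, raw sequence search
1e-20), with best-hit selection, an operon-consistency tiebreak, and
cross-organism conflict resolution by evolutionary proximity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields

import pandas as pd

from osmonet.errors import ConfigurationError, DataError

#: Default organism priority: closest evolutionary relative of a marine
#: cyanobacterial target first (halotolerant cyanobacterium, freshwater
#: cyanobacterium, then progressively more distant bacteria).
DEFAULT_ORGANISM_PRIORITY = ("A_halo", "PCC6803", "P_mari", "C_glut", "E_coli")

EVIDENCE_CHANNELS = ("template", "operon", "ppi", "regulon", "profile")


@dataclass(frozen=True)
class TemplateEntry:
    gene_id: str
    symbol: str
    role: str


@dataclass
class TemplateNetwork:
    """A curated (organism, gene, role) table used as a mapping source."""

    organism: str
    entries: list[TemplateEntry]

    def __post_init__(self) -> None:
        ids = [e.gene_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise DataError(f"duplicate gene ids in template {self.organism}")

    @property
    def gene_ids(self) -> set[str]:
        return {e.gene_id for e in self.entries}

    def role_of(self, gene_id: str) -> TemplateEntry:
        for e in self.entries:
            if e.gene_id == gene_id:
                return e
        raise KeyError(gene_id)


@dataclass(frozen=True)
class HomologyHit:
    """One homology hit from the orthology mapper or the sequence search."""

    query: str
    subject: str
    e_value: float
    bit_score: float
    source_tool: str = "sequence_search"

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise DataError(f"negative E-value for {self.query}->{self.subject}")
        if self.source_tool not in ("orthology_map", "sequence_search"):
            raise DataError(f"unknown source tool {self.source_tool!r}")


@dataclass
class MappingThresholds:
    """Tool-specific E-value cutoffs and the organism preference order."""

    orthology_map_evalue_max: float = 1e-6
    sequence_search_evalue_max: float = 1e-20
    organism_priority: tuple[str, ...] = DEFAULT_ORGANISM_PRIORITY

    def __post_init__(self) -> None:
        if self.orthology_map_evalue_max <= 0 or self.sequence_search_evalue_max <= 0:
            raise ConfigurationError("E-value thresholds must be positive")
        self.organism_priority = tuple(self.organism_priority)

    def passes(self, hit: HomologyHit) -> bool:
        if hit.source_tool == "orthology_map":
            return hit.e_value <= self.orthology_map_evalue_max
        return hit.e_value <= self.sequence_search_evalue_max

    def priority_rank(self, organism: str) -> int:
        try:
            return self.organism_priority.index(organism)
        except ValueError:
            raise ConfigurationError(
                f"organism {organism!r} missing from organism_priority"
            ) from None


@dataclass
class GeneRecord:
    """Per-gene annotation inside a network model."""

    gene: str
    role: str = ""
    organism: str = ""
    source_gene: str = ""
    evidence: set[str] = field(default_factory=set)
    da_score: float | None = None
    e_value: float | None = None
    anchors: dict[str, str] = field(default_factory=dict)  # channel -> anchor id


class NetworkModel:
    """Target-genome genes with role assignments and evidence provenance."""

    def __init__(self) -> None:
        self._members: dict[str, GeneRecord] = {}
        self.warnings: list[str] = []

    def __contains__(self, gene: str) -> bool:
        return gene in self._members

    def __len__(self) -> int:
        return len(self._members)

    @property
    def members(self) -> set[str]:
        return set(self._members)

    def record(self, gene: str) -> GeneRecord:
        return self._members[gene]

    def records(self) -> list[GeneRecord]:
        return [self._members[g] for g in sorted(self._members)]

    def genes_with_evidence(self, tag: str) -> set[str]:
        return {g for g, r in self._members.items() if tag in r.evidence}

    def add(self, rec: GeneRecord) -> None:
        if not rec.evidence:
            raise DataError(f"gene {rec.gene} added without evidence tags")
        if "template" in rec.evidence and not rec.source_gene:
            raise DataError(f"template-tagged gene {rec.gene} lacks a source gene")
        existing = self._members.get(rec.gene)
        if existing is None:
            self._members[rec.gene] = rec
        else:
            existing.evidence |= rec.evidence
            existing.anchors.update(rec.anchors)
            if not existing.role and rec.role:
                existing.role = rec.role

    def copy(self) -> "NetworkModel":
        out = NetworkModel()
        for rec in self.records():
            out._members[rec.gene] = GeneRecord(
                gene=rec.gene, role=rec.role, organism=rec.organism,
                source_gene=rec.source_gene, evidence=set(rec.evidence),
                da_score=rec.da_score, e_value=rec.e_value,
                anchors=dict(rec.anchors),
            )
        out.warnings = list(self.warnings)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records():
            rows.append({
                "gene": rec.gene,
                "role": rec.role,
                "organism": rec.organism,
                "source_gene": rec.source_gene,
                "evidence": ",".join(sorted(rec.evidence)),
                "da_score": "" if rec.da_score is None else f"{rec.da_score:.3f}",
            })
        return pd.DataFrame(
            rows, columns=["gene", "role", "organism", "source_gene",
                           "evidence", "da_score"])


@dataclass(frozen=True)
class MappedPair:
    template_gene: str
    target_gene: str
    e_value: float


@dataclass
class OrganismMapping:
    """Best-hit mapping of one template network onto the target genome."""

    organism: str
    pairs: list[MappedPair]
    template: TemplateNetwork | None = None

    def __len__(self) -> int:
        return len(self.pairs)


def map_template(
    template: TemplateNetwork,
    hits: list[HomologyHit],
    operons=None,
    thr: MappingThresholds | None = None,
) -> OrganismMapping:
    """Map one template network onto the target genome.

    Hits are filtered at the tool-specific threshold; per query the best
    (lowest-E) subject survives. Among equal-E candidates, a subject lying
    in an operon shared with another query's chosen subject wins the tie
    (operon consistency as a tiebreak bonus, not a hard filter); remaining
    ties break lexicographically on the subject id.
    """
    thr = thr or MappingThresholds()
    template_genes = template.gene_ids
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        if h.query in template_genes and thr.passes(h):
            by_query.setdefault(h.query, []).append(h)

    gene_to_operon: dict[str, str] = {}
    if operons is not None:
        gene_to_operon = getattr(operons, "gene_to_operon", operons)

    # First pass: provisional best subject per query (lexicographic ties).
    candidates: dict[str, list[HomologyHit]] = {}
    provisional: dict[str, HomologyHit] = {}
    for q, hs in by_query.items():
        best_e = min(h.e_value for h in hs)
        ties = sorted((h for h in hs if h.e_value == best_e),
                      key=lambda h: h.subject)
        candidates[q] = ties
        provisional[q] = ties[0]

    # Second pass: among equal-E ties prefer a subject co-operonic with
    # another query's chosen subject.
    chosen_operons = {
        gene_to_operon[h.subject]
        for h in provisional.values() if h.subject in gene_to_operon
    }
    pairs = []
    for q in sorted(candidates):
        ties = candidates[q]
        pick = ties[0]
        if len(ties) > 1 and gene_to_operon:
            others = {
                gene_to_operon[h.subject]
                for q2, h in provisional.items()
                if q2 != q and h.subject in gene_to_operon
            }
            for h in ties:
                if gene_to_operon.get(h.subject) in others:
                    pick = h
                    break
        pairs.append(MappedPair(q, pick.subject, pick.e_value))
    del chosen_operons
    return OrganismMapping(template.organism, pairs, template)


def merge_mappings(
    per_organism: list[OrganismMapping],
    thr: MappingThresholds | None = None,
    da_scores: dict[tuple[str, str], float] | None = None,
) -> NetworkModel:
    """Merge per-organism mappings into the initial network model.

    When several template genes land on one target gene the conflict is
    resolved by (1) organism priority (closest relative first), (2) higher
    domain-architecture conservation score, (3) lower E-value, then a
    deterministic lexicographic tiebreak with a warning.
    """
    thr = thr or MappingThresholds()
    da_scores = da_scores or {}
    model = NetworkModel()
    contenders: dict[str, list[tuple]] = {}
    seen: set[tuple] = set()  # dedupe so merging a mapping with itself is identity
    for mapping in per_organism:
        rank = thr.priority_rank(mapping.organism)
        for pair in mapping.pairs:
            key = (mapping.organism, pair.template_gene, pair.target_gene,
                   pair.e_value)
            if key in seen:
                continue
            seen.add(key)
            entry = None
            if mapping.template is not None:
                try:
                    entry = mapping.template.role_of(pair.template_gene)
                except KeyError:
                    entry = None
            contenders.setdefault(pair.target_gene, []).append(
                (rank, pair, mapping.organism, entry))

    for target in sorted(contenders):
        rows = contenders[target]

        def sort_key(row):
            rank, pair, organism, _entry = row
            da = da_scores.get((pair.template_gene, target))
            return (
                rank,
                -(da if da is not None else -1.0),
                pair.e_value,
                pair.template_gene,
            )

        rows.sort(key=sort_key)
        if len(rows) > 1:
            k0, k1 = sort_key(rows[0]), sort_key(rows[1])
            if k0[:3] == k1[:3]:
                msg = (f"unresolved conflict at {target}: "
                       f"{rows[0][1].template_gene} vs {rows[1][1].template_gene}; "
                       f"kept lexicographically smaller source")
                model.warnings.append(msg)
                warnings.warn(msg, stacklevel=2)
        rank, pair, organism, entry = rows[0]
        model.add(GeneRecord(
            gene=target,
            role=entry.role if entry else "",
            organism=organism,
            source_gene=pair.template_gene,
            evidence={"template"},
            da_score=da_scores.get((pair.template_gene, target)),
            e_value=pair.e_value,
        ))
    return model
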