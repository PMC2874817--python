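"""Protein domain-architecture conservation scoring.

True orthologs across related genomes should keep the same domain
architecture (the ordered multiset of domains along the protein), so a
conservation score over mapped gene pairs validates the orthology mapping.
The score is a linear combination of three indices on the two
architectures:

* the Jaccard index over the distinct domain sets (shared content);
* the Goodman-Kruskal gamma over the relative order of first occurrences
  of the shared distinct domains (shared arrangement), rescaled to [0, 1];
* the duplicate index, sum(min copy counts)/sum(max copy counts) over the
  shared distinct domains (shared duplication pattern).

All three lie in [0, 1]; 1 means identical, 0 totally different. Domains
are identified by accession only — coordinates order first occurrences but
are otherwise ignored.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from osmonet.errors import ConfigurationError, DataError
from osmonet.template_mapping import NetworkModel


@dataclass
class DomainArchitecture:
    """Ordered multiset of domain accessions for one protein."""

    gene: str
    domains: list[str]
    coords: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.coords is not None:
            if len(self.coords) != len(self.domains):
                raise DataError(f"{self.gene}: coords/domains length mismatch")
            order = sorted(range(len(self.coords)),
                           key=lambda i: self.coords[i])
            self.domains = [self.domains[i] for i in order]
            self.coords = [self.coords[i] for i in order]
            for (s1, e1), (s2, e2) in zip(self.coords, self.coords[1:]):
                if s2 < e1:
                    raise DataError(f"{self.gene}: overlapping domains")

    @property
    def distinct(self) -> set[str]:
        return set(self.domains)

    @property
    def copy_counts(self) -> Counter:
        return Counter(self.domains)

    def first_occurrence_order(self) -> dict[str, int]:
        order: dict[str, int] = {}
        for i, d in enumerate(self.domains):
            order.setdefault(d, i)
        return order


@dataclass
class DAScoreWeights:
    """Weights of the three indices; non-negative, summing to 1."""

    w_jaccard: float = 1.0 / 3.0
    w_gamma: float = 1.0 / 3.0
    w_dup: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        ws = (self.w_jaccard, self.w_gamma, self.w_dup)
        if any(w < 0 for w in ws):
            raise ConfigurationError("index weights must be non-negative")
        if abs(sum(ws) - 1.0) > 1e-9:
            raise ConfigurationError("index weights must sum to 1")


def jaccard_index(a: DomainArchitecture, b: DomainArchitecture) -> float:
    """|distinct(a) & distinct(b)| / |distinct(a) | distinct(b)|.

    Two empty architectures are identically empty -> 1.
    """
    da, db = a.distinct, b.distinct
    if not da and not db:
        return 1.0
    return len(da & db) / len(da | db)


def gk_gamma(a: DomainArchitecture, b: DomainArchitecture) -> float:
    """Goodman-Kruskal gamma over shared-domain first-occurrence order.

    Counts concordant/discordant unordered pairs of shared distinct domains
    (same vs opposite relative order of first occurrence in the two
    architectures); raw gamma = (Nc - Nd)/(Nc + Nd) is rescaled to [0, 1]
    as (gamma + 1)/2. Fewer than two shared domains give no arrangement
    evidence against conservation -> 1.
    """
    shared = sorted(a.distinct & b.distinct)
    if len(shared) < 2:
        return 1.0
    oa = a.first_occurrence_order()
    ob = b.first_occurrence_order()
    n_c = n_d = 0
    for d1, d2 in combinations(shared, 2):
        same_a = oa[d1] < oa[d2]
        same_b = ob[d1] < ob[d2]
        if same_a == same_b:
            n_c += 1
        else:
            n_d += 1
    gamma = (n_c - n_d) / (n_c + n_d)
    return (gamma + 1.0) / 2.0


def duplicate_index(a: DomainArchitecture, b: DomainArchitecture) -> float:
    """sum_d min(c_a, c_b) / sum_d max(c_a, c_b) over shared domains.

    No shared domains -> 0, unless both architectures are empty -> 1.
    """
    ca, cb = a.copy_counts, b.copy_counts
    shared = set(ca) & set(cb)
    if not shared:
        return 1.0 if not ca and not cb else 0.0
    num = sum(min(ca[d], cb[d]) for d in shared)
    den = sum(max(ca[d], cb[d]) for d in shared)
    return num / den


def da_score(a: DomainArchitecture, b: DomainArchitecture,
             w: DAScoreWeights | None = None) -> float:
    """Weighted combination of the three indices, in [0, 1].

    Identical architectures score 1; architectures sharing no domain score
    0 (the no-shared-content case overrides the vacuous-gamma convention,
    keeping '0 means totally different' exact).
    """
    w = w or DAScoreWeights()
    da_, db_ = a.distinct, b.distinct
    if not da_ and not db_:
        return 1.0
    if not (da_ & db_):
        return 0.0
    return (w.w_jaccard * jaccard_index(a, b)
            + w.w_gamma * gk_gamma(a, b)
            + w.w_dup * duplicate_index(a, b))


@dataclass
class PairValidation:
    source_gene: str
    target_gene: str
    score: float
    flagged: bool
    missing_in_target: list[str] = field(default_factory=list)
    extra_in_target: list[str] = field(default_factory=list)
    copy_count_diffs: list[str] = field(default_factory=list)


@dataclass
class DAValidationSection:
    pairs: list[PairValidation]
    skipped: list[tuple[str, str]] = field(default_factory=list)
    threshold: float = 0.9

    @property
    def n_conserved(self) -> int:
        return sum(not p.flagged for p in self.pairs)

    @property
    def n_flagged(self) -> int:
        return sum(p.flagged for p in self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "source_gene": p.source_gene,
            "target_gene": p.target_gene,
            "da_score": f"{p.score:.3f}",
            "flagged": "X" if p.flagged else "",
            "missing_in_target": ",".join(p.missing_in_target),
            "extra_in_target": ",".join(p.extra_in_target),
            "copy_count_diffs": ",".join(p.copy_count_diffs),
        } for p in self.pairs]
        return pd.DataFrame(rows, columns=[
            "source_gene", "target_gene", "da_score", "flagged",
            "missing_in_target", "extra_in_target", "copy_count_diffs"])


def validate_model_pairs(
    model: NetworkModel,
    architectures: dict[str, DomainArchitecture],
    threshold: float = 0.9,
    weights: DAScoreWeights | None = None,
) -> DAValidationSection:
    """Score every template-mapped (source, target) pair of the model.

    Pairs scoring below ``threshold`` are flagged with the domain
    accessions missing from / extra in the target architecture and any
    copy-count differences. Pairs lacking an architecture on either side
    are skipped and listed.
    """
    weights = weights or DAScoreWeights()
    pairs: list[PairValidation] = []
    skipped: list[tuple[str, str]] = []
    for rec in model.records():
        if "template" not in rec.evidence or not rec.source_gene:
            continue
        arch_s = architectures.get(rec.source_gene)
        arch_t = architectures.get(rec.gene)
        if arch_s is None or arch_t is None:
            skipped.append((rec.source_gene, rec.gene))
            continue
        score = da_score(arch_s, arch_t, weights)
        flagged = score < threshold
        missing = sorted(arch_s.distinct - arch_t.distinct)
        extra = sorted(arch_t.distinct - arch_s.distinct)
        cs, ct = arch_s.copy_counts, arch_t.copy_counts
        diffs = [f"{d}:{cs[d]}vs{ct[d]}"
                 for d in sorted(set(cs) & set(ct)) if cs[d] != ct[d]]
        pairs.append(PairValidation(
            rec.source_gene, rec.gene, score, flagged,
            missing_in_target=missing if flagged else [],
            extra_in_target=extra if flagged else [],
            copy_count_diffs=diffs if flagged else [],
        ))
    return DAValidationSection(pairs=pairs, skipped=skipped,
                               threshold=threshold)
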