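"""Curated data fixtures shipped with the package.

Two literature-curated tables are bundled: the five template networks
(63 genes across five organisms) and the published initial network model for
the target genome (28 gene-to-gene assignments with operon context and
domain-architecture conservation scores). Helpers rebuild derived inputs —
a homology-hit table and an operon table consistent with the initial-model
table — so the merge and recruitment stages can be regression-tested
against the published assignments.
"""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

from osmonet.io import read_tsv
from osmonet.template_mapping import (
    HomologyHit,
    MappedPair,
    OrganismMapping,
    TemplateEntry,
    TemplateNetwork,
)

TARGET_PREFIX = "SYNW"


def _data_path(name: str):
    return resources.files("osmonet.data").joinpath(name)


def load_template_networks() -> dict[str, TemplateNetwork]:
    """The five curated template networks, keyed by organism label."""
    with resources.as_file(_data_path("template_networks.tsv")) as p:
        df = read_tsv(p, columns=["organism", "gene_id", "symbol", "role"])
    out: dict[str, TemplateNetwork] = {}
    for organism, sub in df.groupby("organism", sort=True):
        entries = [TemplateEntry(r.gene_id, r.symbol, r.role)
                   for r in sub.itertuples(index=False)]
        out[organism] = TemplateNetwork(organism, entries)
    return out


def load_initial_model_table() -> pd.DataFrame:
    """The published 28-row initial model (source gene, target gene, operon,
    domain-architecture score, source organism)."""
    with resources.as_file(_data_path("initial_model.tsv")) as p:
        return read_tsv(p, columns=["source_gene", "source_symbol",
                                    "target_gene", "operon", "da_score",
                                    "organism"])


def hits_from_initial_model(e_value: float = 1e-30,
                            source_tool: str = "sequence_search",
                            ) -> dict[str, list[HomologyHit]]:
    """Build a per-organism homology-hit table from the initial-model rows."""
    df = load_initial_model_table()
    hits: dict[str, list[HomologyHit]] = {}
    for r in df.itertuples(index=False):
        hits.setdefault(r.organism, []).append(
            HomologyHit(r.source_gene, r.target_gene, e_value, 200.0,
                        source_tool))
    return hits


def mappings_from_initial_model(e_value: float = 1e-30,
                                ) -> list[OrganismMapping]:
    """Per-organism mappings taken verbatim from the initial-model table."""
    df = load_initial_model_table()
    out = []
    for organism, sub in df.groupby("organism", sort=True):
        pairs = [MappedPair(r.source_gene, r.target_gene, e_value)
                 for r in sub.itertuples(index=False)]
        out.append(OrganismMapping(organism, pairs, template=None))
    return out


_RANGE = re.compile(rf"^{TARGET_PREFIX}(\d+)-(\d+)$")


def expand_operon_range(label: str) -> list[str]:
    """Expand an operon label like 'SYNW2165-2170' into its gene ids."""
    m = _RANGE.match(label)
    if not m:
        return [label] if label else []
    lo, hi = m.group(1), m.group(2)
    width = len(lo)
    return [f"{TARGET_PREFIX}{i:0{width}d}" for i in range(int(lo), int(hi) + 1)]


def operon_table_from_initial_model() -> dict[str, list[str]]:
    """Operon table consistent with the initial model's operon column."""
    df = load_initial_model_table()
    operons: dict[str, list[str]] = {}
    for label in df["operon"]:
        if label and label not in operons:
            operons[label] = expand_operon_range(label)
    return operons
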