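"""Synthetic-world generator with planted ground truth.

Emulates every input of the pipeline — template networks, homology hits,
operons, protein-protein interactions, a transferable regulon,
phylogenetic-profile presence tables, domain architectures, expression
fold changes, pathway annotations — around a set of planted functional
modules whose genes co-occur across the reference-genome panel, co-locate
in operons, interact, and are enriched for differential expression. The
planted truth (module membership, ortholog pairs, DE genes, the enriched
pathway) is retrievable, so every downstream stage can be scored without
external data.

No sequences are simulated: orthology is represented directly by hit
tables with E-values straddling the mapping thresholds (true pairs below,
decoys above), and profiles are drawn as presence/absence bits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from osmonet.domain_architecture import DomainArchitecture, da_score
from osmonet.errors import ConfigurationError
from osmonet.expansion import OperonTable, PPIList, RegulonDefinition
from osmonet.io import write_blast_tabular, write_rows, write_tsv
from osmonet.phylo_profiles import PanelMarginals
from osmonet.template_mapping import (
    HomologyHit,
    TemplateEntry,
    TemplateNetwork,
)

#: Per-organism template sizes mirroring the curated fixture (63 genes).
DEFAULT_TEMPLATE_SIZES = {
    "A_halo": 3, "C_glut": 3, "E_coli": 37, "P_mari": 2, "PCC6803": 18,
}


@dataclass
class WorldConfig:
    """Parameters of the synthetic world.

    The defaults reproduce the study conditions: a 2520-gene target genome
    profiled against 810 reference genomes, 102 differentially expressed
    genes, a 103-member regulon of which 41 members have a target-genome
    ortholog, and 63 template-to-target ortholog pairs of which 7 carry a
    perturbed domain architecture.
    """

    n_target_genes: int = 2520
    n_reference_genomes: int = 810
    n_modules: int = 12
    module_size_range: tuple[int, int] = (6, 14)
    ortholog_retention: float = 0.9
    background_presence: float = 0.3
    n_de_genes: int = 102
    de_enrichment_in_model: float = 0.25
    fold_change_range: tuple[float, float] = (0.125, 8.0)
    seed: int = 0
    # shape of the auxiliary tables
    module_genome_rate: float = 0.5
    template_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE_SIZES))
    #: share of template targets drawn from planted modules; the rest are
    #: background genes.
    template_module_fraction: float = 1.0
    #: per-genome flip rate of a non-target module gene's profile relative
    #: to its parent target gene (profile-twin noise).
    companion_noise: float = 0.03
    regulator: str = "sigma38"
    regulon_organism: str = "E_coli"
    n_regulon_members: int = 103
    n_regulon_orthologs: int = 41
    operon_size_range: tuple[int, int] = (2, 6)
    background_operon_fraction: float = 0.3
    n_ppi_edges: int = 950
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 60)
    planted_pathway_size: int = 30
    planted_pathway_module_fraction: float = 0.9
    n_da_perturbed: int = 7
    decoy_hit_rate: float = 2.0

    def __post_init__(self) -> None:
        probs = (self.ortholog_retention, self.background_presence,
                 self.de_enrichment_in_model, self.module_genome_rate,
                 self.background_operon_fraction,
                 self.planted_pathway_module_fraction,
                 self.template_module_fraction, self.companion_noise)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        lo, hi = self.module_size_range
        if lo < 2 or hi < lo:
            raise ConfigurationError("module sizes must be >= 2 and ordered")
        if self.n_modules * hi > self.n_target_genes:
            raise ConfigurationError(
                f"{self.n_modules} modules of up to {hi} genes exceed "
                f"{self.n_target_genes} target genes")
        fl, fh = self.fold_change_range
        if not (0 < fl <= 0.5 and fh >= 2.0):
            raise ConfigurationError(
                "fold_change_range must bracket the DE cutoffs (low <= 0.5,"
                " high >= 2.0)")
        if self.n_regulon_orthologs > self.n_regulon_members:
            raise ConfigurationError("more regulon orthologs than members")
        if self.n_de_genes > self.n_target_genes:
            raise ConfigurationError("more DE genes than target genes")
        total_templates = sum(self.template_sizes.values())
        if total_templates > self.n_target_genes:
            raise ConfigurationError("more template genes than target genes")
        if self.n_da_perturbed > total_templates:
            raise ConfigurationError("more perturbed pairs than template pairs")


@dataclass
class SyntheticWorld:
    """All pipeline inputs plus the planted ground truth."""

    config: WorldConfig
    genes: list[str]
    genomes: list[str]
    modules: dict[str, list[str]]
    gene_module: dict[str, str]
    presence: pd.DataFrame
    templates: dict[str, TemplateNetwork]
    true_pairs: dict[str, list[tuple[str, str]]]
    hits: dict[str, list[HomologyHit]]
    operons: OperonTable
    ppi: PPIList
    regulon: RegulonDefinition
    regulon_hits: list[HomologyHit]
    regulon_true_targets: dict[str, str]
    architectures: dict[str, DomainArchitecture]
    da_perturbed_pairs: list[tuple[str, str]]
    expression: pd.Series
    de_genes: set[str]
    pathway_annotation: pd.DataFrame
    planted_pathway: str

    def marginals(self) -> PanelMarginals:
        return PanelMarginals.from_matrix(self.presence)

    @property
    def module_genes(self) -> set[str]:
        return set(self.gene_module)

    def write(self, outdir: str | os.PathLike) -> None:
        """Serialize every input table (deterministic byte-for-byte)."""
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)

        write_rows(
            [(org, e.gene_id, e.symbol, e.role)
             for org in sorted(self.templates)
             for e in self.templates[org].entries],
            ["organism", "gene_id", "symbol", "role"],
            os.path.join(outdir, "template_networks.tsv"))

        for org in sorted(self.hits):
            for tool in ("orthology_map", "sequence_search"):
                sub = [h for h in self.hits[org] if h.source_tool == tool]
                df = pd.DataFrame(
                    [(h.query, h.subject, h.e_value, h.bit_score)
                     for h in sub],
                    columns=["qseqid", "sseqid", "evalue", "bitscore"])
                write_blast_tabular(
                    df, os.path.join(outdir, f"hits_{org}.{tool}.tsv"))
        for tool in ("orthology_map", "sequence_search"):
            sub = [h for h in self.regulon_hits if h.source_tool == tool]
            df = pd.DataFrame(
                [(h.query, h.subject, h.e_value, h.bit_score) for h in sub],
                columns=["qseqid", "sseqid", "evalue", "bitscore"])
            write_blast_tabular(
                df, os.path.join(outdir, f"regulon_hits.{tool}.tsv"))

        write_rows(
            [(op, g, rank)
             for op in sorted(self.operons.operons)
             for rank, g in enumerate(self.operons.members(op), start=1)],
            ["operon_id", "gene_id", "rank"],
            os.path.join(outdir, "operons.tsv"))

        prof = self.presence.reset_index().rename(columns={"index": "gene"})
        write_tsv(prof, os.path.join(outdir, "profiles.tsv"))

        write_rows(sorted(self.ppi.edges), ["gene_a", "gene_b"],
                   os.path.join(outdir, "ppi.tsv"))

        write_rows(
            [(self.regulon.regulator, self.regulon.organism, m)
             for m in self.regulon.members],
            ["regulator", "organism", "member"],
            os.path.join(outdir, "regulon.tsv"))

        write_rows(
            [(g, d, s, e)
             for g in sorted(self.architectures)
             for d, (s, e) in zip(self.architectures[g].domains,
                                  self.architectures[g].coords)],
            ["gene", "accession", "start", "end"],
            os.path.join(outdir, "domains.tsv"))

        write_rows(
            [(g, f"{self.expression[g]:.6f}") for g in self.genes],
            ["gene", "fold_change"],
            os.path.join(outdir, "expression.tsv"))

        write_tsv(self.pathway_annotation,
                  os.path.join(outdir, "pathways.tsv"))

        write_rows(
            [(m, g) for m in sorted(self.modules)
             for g in self.modules[m]],
            ["module", "gene"],
            os.path.join(outdir, "truth_modules.tsv"))
        write_rows(
            [(org, q, t) for org in sorted(self.true_pairs)
             for q, t in self.true_pairs[org]],
            ["organism", "template_gene", "target_gene"],
            os.path.join(outdir, "truth_orthologs.tsv"))
        write_rows([(g,) for g in sorted(self.de_genes)], ["gene"],
                   os.path.join(outdir, "truth_de_genes.tsv"))


def true_orthologs(world: SyntheticWorld, organism: str,
                   ) -> list[tuple[str, str]]:
    """The planted (template gene, target gene) pairs for one organism."""
    try:
        return list(world.true_pairs[organism])
    except KeyError:
        raise LookupError(
            f"unknown organism {organism!r}; have "
            f"{sorted(world.true_pairs)}") from None


def _log_uniform(rng: np.random.Generator, lo_exp: float, hi_exp: float,
                 size: int | None = None):
    return 10.0 ** rng.uniform(lo_exp, hi_exp, size)


def _chunk(seq: list[str], rng: np.random.Generator,
           size_range: tuple[int, int]) -> list[list[str]]:
    """Split a list into consecutive chunks with random sizes in range."""
    out, i = [], 0
    lo, hi = size_range
    while i < len(seq):
        k = int(rng.integers(lo, hi + 1))
        chunk = seq[i:i + k]
        if len(chunk) >= 2:
            out.append(chunk)
        i += k
    return out


def build_world(config: WorldConfig) -> SyntheticWorld:  # noqa: C901
    """Generate a synthetic world; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_g, n_ref = config.n_target_genes, config.n_reference_genomes
    genes = [f"T{i:04d}" for i in range(n_g)]
    genomes = [f"G{j:03d}" for j in range(n_ref)]

    # ---- planted modules -------------------------------------------------
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, config.n_modules)
    perm = [genes[i] for i in rng.permutation(n_g)]
    modules: dict[str, list[str]] = {}
    gene_module: dict[str, str] = {}
    pos = 0
    for k, size in enumerate(sizes):
        mid = f"M{k:02d}"
        members = sorted(perm[pos:pos + int(size)])
        modules[mid] = members
        for g in members:
            gene_module[g] = mid
        pos += int(size)

    # ---- template targets (chosen first: profiles are built around them) -
    module_pool = [g for g in perm if g in gene_module]
    # re-shuffle so template targets spread across modules instead of
    # swallowing the first modules whole (perm ordered the module blocks)
    module_pool = [module_pool[int(i)]
                   for i in rng.permutation(len(module_pool))]
    background_pool = [g for g in perm if g not in gene_module]
    total_templates = sum(config.template_sizes.values())
    n_mod_targets = min(int(round(config.template_module_fraction
                                  * total_templates)), len(module_pool))
    combined = (module_pool[:n_mod_targets]
                + background_pool[:total_templates - n_mod_targets])
    target_pool = [combined[int(i)] for i in rng.permutation(len(combined))]
    target_set = set(target_pool)

    # ---- ortholog presence table (phylogenetic profiles) ----------------
    # Template targets inside a module carry the module's clade pattern
    # with independent dropout; the remaining module genes are profile
    # companions — near-copies of one target's profile — mirroring the
    # tightly co-inherited neighbours that co-evolution recruitment is
    # meant to find. Background genes have i.i.d. presence.
    presence = (rng.random((n_g, n_ref))
                < config.background_presence).astype(np.int8)
    gene_idx = {g: i for i, g in enumerate(genes)}
    for mid in sorted(modules):
        clade = rng.random(n_ref) < config.module_genome_rate
        targets_here = [g for g in modules[mid] if g in target_set]
        for g in targets_here:
            kept = rng.random(n_ref) < config.ortholog_retention
            presence[gene_idx[g]] = (clade & kept).astype(np.int8)
        for g in modules[mid]:
            if g in target_set:
                continue
            if targets_here:
                parent = targets_here[int(rng.integers(len(targets_here)))]
                flips = rng.random(n_ref) < config.companion_noise
                presence[gene_idx[g]] = (
                    presence[gene_idx[parent]] ^ flips.astype(np.int8))
            else:
                kept = rng.random(n_ref) < config.ortholog_retention
                presence[gene_idx[g]] = (clade & kept).astype(np.int8)
    presence_df = pd.DataFrame(presence, index=genes, columns=genomes)

    templates: dict[str, TemplateNetwork] = {}
    true_pairs: dict[str, list[tuple[str, str]]] = {}
    cursor = 0
    for org in sorted(config.template_sizes):
        count = config.template_sizes[org]
        targets = target_pool[cursor:cursor + count]
        cursor += count
        entries, pairs = [], []
        for i, tgt in enumerate(targets):
            q = f"{org}_g{i:03d}"
            role = (f"planted module {gene_module[tgt]} component"
                    if tgt in gene_module else "background component")
            entries.append(TemplateEntry(q, f"{org}{i:03d}", role))
            pairs.append((q, tgt))
        templates[org] = TemplateNetwork(org, entries)
        true_pairs[org] = pairs

    # ---- homology hits: true pairs below threshold, decoys above ---------
    hits: dict[str, list[HomologyHit]] = {}
    for org in sorted(templates):
        org_hits: list[HomologyHit] = []
        for q, tgt in true_pairs[org]:
            e = float(_log_uniform(rng, -50, -21))
            tool = ("orthology_map", "sequence_search")[int(rng.integers(2))]
            org_hits.append(HomologyHit(q, tgt, e, round(-4.0 * np.log10(e), 1),
                                        tool))
            for _ in range(int(rng.poisson(config.decoy_hit_rate))):
                decoy = genes[int(rng.integers(n_g))]
                if decoy == tgt:
                    continue
                e_d = float(_log_uniform(rng, -19, -2))
                org_hits.append(HomologyHit(
                    q, decoy, e_d, round(-4.0 * np.log10(e_d), 1),
                    "sequence_search"))
        hits[org] = org_hits

    # ---- operons: module genes co-operonic, plus background operons ------
    operon_map: dict[str, list[str]] = {}
    op_counter = 0
    for mid in sorted(modules):
        for chunk in _chunk(modules[mid], rng, config.operon_size_range):
            operon_map[f"op{op_counter:04d}"] = chunk
            op_counter += 1
    n_bg_operon = int(config.background_operon_fraction * len(background_pool))
    for chunk in _chunk(background_pool[:n_bg_operon], rng,
                        config.operon_size_range):
        operon_map[f"op{op_counter:04d}"] = chunk
        op_counter += 1
    operons = OperonTable(operon_map)

    # ---- protein-protein interactions ------------------------------------
    edge_set: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    for mid in sorted(modules):
        members = modules[mid]
        for _ in range(len(members)):
            i, j = rng.integers(len(members)), rng.integers(len(members))
            if i == j:
                continue
            e = tuple(sorted((members[int(i)], members[int(j)])))
            if e not in edge_set:
                edge_set.add(e)
                edges.append(e)
    while len(edges) < config.n_ppi_edges:
        i, j = rng.integers(n_g), rng.integers(n_g)
        if i == j:
            continue
        e = tuple(sorted((genes[int(i)], genes[int(j)])))
        if e not in edge_set:
            edge_set.add(e)
            edges.append(e)
    ppi = PPIList(edges)

    # ---- regulon with planted ortholog subset -----------------------------
    members = [f"{config.regulon_organism}_r{i:03d}"
               for i in range(config.n_regulon_members)]
    regulon = RegulonDefinition(config.regulator, config.regulon_organism,
                                members)
    mapped_members = members[:config.n_regulon_orthologs]
    # a few regulon targets corroborate genes already in the initial model
    org_pairs = true_pairs.get(config.regulon_organism, [])
    n_corr = min(3, len(org_pairs), len(mapped_members))
    corroborate = [t for _, t in org_pairs[:n_corr]]
    fresh_idx = rng.permutation(n_g)
    used = set(corroborate)
    fresh_targets = [genes[int(i)] for i in fresh_idx
                     if genes[int(i)] not in used]
    regulon_true_targets: dict[str, str] = {}
    regulon_hits: list[HomologyHit] = []
    for i, m in enumerate(mapped_members):
        tgt = corroborate[i] if i < len(corroborate) else fresh_targets[i]
        regulon_true_targets[m] = tgt
        e = float(_log_uniform(rng, -50, -21))
        tool = ("orthology_map", "sequence_search")[int(rng.integers(2))]
        regulon_hits.append(HomologyHit(m, tgt, e,
                                        round(-4.0 * np.log10(e), 1), tool))
    for m in members[config.n_regulon_orthologs:]:
        if rng.random() < 0.5:
            decoy = genes[int(rng.integers(n_g))]
            e_d = float(_log_uniform(rng, -19, -2))
            regulon_hits.append(HomologyHit(
                m, decoy, e_d, round(-4.0 * np.log10(e_d), 1),
                "sequence_search"))

    # ---- domain architectures ---------------------------------------------
    pool = [f"PF{i:05d}" for i in range(1, 401)]
    architectures: dict[str, DomainArchitecture] = {}

    def _coords(doms: list[str]) -> list[tuple[int, int]]:
        return [(i * 100 + 1, i * 100 + 90) for i in range(len(doms))]

    all_pairs = [(q, t) for org in sorted(true_pairs)
                 for q, t in true_pairs[org]]
    perturbed_idx = set(
        int(i) for i in rng.choice(len(all_pairs), config.n_da_perturbed,
                                   replace=False))
    da_perturbed_pairs: list[tuple[str, str]] = []
    for pi, (q, tgt) in enumerate(all_pairs):
        n_dom = int(rng.integers(2, 5))
        doms = [pool[int(i)]
                for i in rng.choice(len(pool), n_dom, replace=False)]
        if rng.random() < 0.3:  # occasional tandem duplication, shared
            doms = doms + [doms[int(rng.integers(len(doms)))]]
        architectures[q] = DomainArchitecture(q, list(doms), _coords(doms))
        tdoms = list(doms)
        if pi in perturbed_idx:
            # degrade until the pair drops below the conservation threshold
            while tdoms and da_score(
                    architectures[q],
                    DomainArchitecture(tgt, tdoms, _coords(tdoms))) >= 0.9:
                if len(tdoms) > 1 and rng.random() < 0.5:
                    tdoms.pop(int(rng.integers(len(tdoms))))
                else:
                    tdoms = tdoms + [tdoms[int(rng.integers(len(tdoms)))]] * 2
                    # tandem extra copies perturb the duplicate index
                if len(tdoms) > 12:
                    break
            da_perturbed_pairs.append((q, tgt))
        architectures[tgt] = DomainArchitecture(tgt, tdoms, _coords(tdoms))
    template_targets = {t for _, t in all_pairs}
    for g in genes:
        if g in template_targets:
            continue
        n_dom = int(rng.integers(1, 5))
        doms = [pool[int(i)]
                for i in rng.choice(len(pool), n_dom, replace=False)]
        architectures[g] = DomainArchitecture(g, doms, _coords(doms))

    # ---- expression with DE planted preferentially in modules ------------
    fl, fh = config.fold_change_range
    module_gene_list = sorted(gene_module)
    de_flags = rng.random(len(module_gene_list)) < config.de_enrichment_in_model
    de_from_modules = [g for g, f in zip(module_gene_list, de_flags) if f]
    if len(de_from_modules) > config.n_de_genes:
        keep = rng.choice(len(de_from_modules), config.n_de_genes,
                          replace=False)
        de_from_modules = [de_from_modules[int(i)] for i in sorted(keep)]
    n_rest = config.n_de_genes - len(de_from_modules)
    non_module = [g for g in genes if g not in gene_module]
    rest_idx = rng.choice(len(non_module), n_rest, replace=False)
    de_genes = set(de_from_modules) | {non_module[int(i)]
                                       for i in sorted(rest_idx)}

    fc = np.exp(rng.normal(0.0, 0.25, n_g))
    fc = np.clip(fc, 0.5 * 1.04, 2.0 * 0.96)  # non-DE strictly inside (0.5, 2)
    expression = pd.Series(fc, index=genes)
    for g in sorted(de_genes):
        if rng.random() < 0.5:
            expression[g] = float(_log_uniform(rng, np.log10(2.0),
                                               np.log10(fh)))
        else:
            expression[g] = float(_log_uniform(rng, np.log10(fl),
                                               np.log10(0.5)))

    # ---- pathway annotation with one planted enriched pathway ------------
    rows: list[tuple[str, str]] = []
    n_from_model = int(round(config.planted_pathway_size
                             * config.planted_pathway_module_fraction))
    planted_members = list(dict.fromkeys(
        [t for _, t in all_pairs] + module_pool))[:n_from_model]
    n_bg = config.planted_pathway_size - len(planted_members)
    bg_idx = rng.choice(len(background_pool), max(n_bg, 0), replace=False)
    planted_members += [background_pool[int(i)] for i in sorted(bg_idx)]
    planted_id = "pw_planted"
    rows += [(g, planted_id) for g in sorted(planted_members)]
    plo, phi = config.pathway_size_range
    for k in range(config.n_pathways - 1):
        size = int(rng.integers(plo, phi + 1))
        idx = rng.choice(n_g, size, replace=False)
        rows += [(genes[int(i)], f"pw{k:03d}") for i in sorted(idx)]
    pathway_annotation = pd.DataFrame(rows, columns=["gene", "pathway"])

    return SyntheticWorld(
        config=config, genes=genes, genomes=genomes, modules=modules,
        gene_module=gene_module, presence=presence_df, templates=templates,
        true_pairs=true_pairs, hits=hits, operons=operons, ppi=ppi,
        regulon=regulon, regulon_hits=regulon_hits,
        regulon_true_targets=regulon_true_targets,
        architectures=architectures, da_perturbed_pairs=da_perturbed_pairs,
        expression=expression, de_genes=de_genes,
        pathway_annotation=pathway_annotation, planted_pathway=planted_id,
    )


def scaled_down_config(seed: int = 0, **overrides) -> WorldConfig:
    """Desk-scale world (300 genes, 60 genomes) for fast tests and demos."""
    params = dict(
        n_target_genes=300, n_reference_genomes=60, n_modules=10,
        module_size_range=(8, 14), n_de_genes=30, n_ppi_edges=120,
        n_regulon_members=40, n_regulon_orthologs=15,
        n_pathways=8, pathway_size_range=(8, 30), planted_pathway_size=20,
        seed=seed,
    )
    params.update(overrides)
    return WorldConfig(**params)
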