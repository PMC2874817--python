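"""End-to-end orchestration: load tables, map, expand, validate, report.

The pipeline consumes a directory of interchange tables (the layout
written by :meth:`osmonet.synthetic_world.SyntheticWorld.write`, or any
directory following the same naming convention), runs every stage, and
writes the expanded model, validation reports, enrichment table, network
exports and a run manifest into an output directory. All outputs except
the manifest (which records wall-clock timings) are byte-deterministic
given identical inputs and configuration.
"""

from __future__ import annotations

import glob
import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from osmonet import __version__
from osmonet.domain_architecture import (
    DAScoreWeights,
    DomainArchitecture,
    validate_model_pairs,
)
from osmonet.errors import ConfigurationError, DataError
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
from osmonet.io import read_blast_tabular, read_tsv, write_tsv
from osmonet.phylo_profiles import RelatednessParams, recruit_by_profile
from osmonet.template_mapping import (
    HomologyHit,
    MappingThresholds,
    NetworkModel,
    TemplateEntry,
    TemplateNetwork,
    map_template,
    merge_mappings,
)
from osmonet.validation_stats import (
    DECallParams,
    call_de,
    pathway_enrichment,
    validate_channels,
)

ALL_CHANNELS = ("operon", "ppi", "regulon", "profile")


@dataclass
class PipelineConfig:
    """Paths to the input tables plus every stage's tunable parameters."""

    world_dir: str
    output_dir: str
    thresholds: MappingThresholds = field(default_factory=MappingThresholds)
    relatedness: RelatednessParams = field(default_factory=RelatednessParams)
    da_weights: DAScoreWeights = field(default_factory=DAScoreWeights)
    da_threshold: float = 0.9
    de_params: DECallParams = field(default_factory=DECallParams)
    enabled_channels: tuple[str, ...] = ALL_CHANNELS
    enrichment_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.enabled_channels) - set(ALL_CHANNELS)
        if bad:
            raise ConfigurationError(f"unknown channels: {sorted(bad)}")
        self.enabled_channels = tuple(self.enabled_channels)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kw: dict = {}
        kw["world_dir"] = raw.get("world_dir", ".")
        kw["output_dir"] = raw.get("output_dir", "osmonet_out")
        thr = raw.get("thresholds", {})
        kw["thresholds"] = MappingThresholds(**thr) if thr else MappingThresholds()
        rel = raw.get("relatedness", {})
        kw["relatedness"] = RelatednessParams(**rel) if rel else RelatednessParams()
        daw = raw.get("da_weights", {})
        kw["da_weights"] = DAScoreWeights(**daw) if daw else DAScoreWeights()
        kw["da_threshold"] = float(raw.get("da_threshold", 0.9))
        de = raw.get("de_params", {})
        kw["de_params"] = DECallParams(**de) if de else DECallParams()
        kw["enabled_channels"] = tuple(raw.get("enabled_channels", ALL_CHANNELS))
        kw["enrichment_alpha"] = float(raw.get("enrichment_alpha", 0.05))
        kw["seed"] = int(raw.get("seed", 0))
        kw.update(overrides)
        return cls(**kw)

    def canonical(self) -> dict:
        d = {
            "world_dir": self.world_dir,
            "output_dir": self.output_dir,
            "thresholds": asdict(self.thresholds),
            "relatedness": asdict(self.relatedness),
            "da_weights": asdict(self.da_weights),
            "da_threshold": self.da_threshold,
            "de_params": asdict(self.de_params),
            "enabled_channels": list(self.enabled_channels),
            "enrichment_alpha": self.enrichment_alpha,
            "seed": self.seed,
        }
        return d


# ---------------------------------------------------------------- loaders

def load_templates(world_dir: str) -> dict[str, TemplateNetwork]:
    df = read_tsv(os.path.join(world_dir, "template_networks.tsv"),
                  columns=["organism", "gene_id", "symbol", "role"])
    out = {}
    for organism, sub in df.groupby("organism", sort=True):
        out[organism] = TemplateNetwork(
            organism,
            [TemplateEntry(r.gene_id, r.symbol, r.role)
             for r in sub.itertuples(index=False)])
    return out


def _load_hit_files(pattern: str) -> list[HomologyHit]:
    hits: list[HomologyHit] = []
    for path in sorted(glob.glob(pattern)):
        tool = "orthology_map" if "orthology_map" in os.path.basename(path) \
            else "sequence_search"
        df = read_blast_tabular(path)
        hits += [HomologyHit(r.qseqid, r.sseqid, r.evalue, r.bitscore, tool)
                 for r in df.itertuples(index=False)]
    return hits


def load_hits(world_dir: str, organism: str) -> list[HomologyHit]:
    return _load_hit_files(os.path.join(world_dir, f"hits_{organism}.*.tsv"))


def load_regulon(world_dir: str) -> tuple[RegulonDefinition, list[HomologyHit]]:
    df = read_tsv(os.path.join(world_dir, "regulon.tsv"),
                  columns=["regulator", "organism", "member"])
    if df.empty:
        raise DataError("empty regulon table")
    reg = RegulonDefinition(df["regulator"].iloc[0], df["organism"].iloc[0],
                            list(df["member"]))
    hits = _load_hit_files(os.path.join(world_dir, "regulon_hits.*.tsv"))
    return reg, hits


def load_operons(world_dir: str) -> OperonTable:
    df = read_tsv(os.path.join(world_dir, "operons.tsv"),
                  columns=["operon_id", "gene_id", "rank"])
    table: dict[str, list[str]] = {}
    for r in df.sort_values(["operon_id", "rank"],
                            key=lambda s: s if s.name != "rank"
                            else s.astype(int)).itertuples(index=False):
        table.setdefault(r.operon_id, []).append(r.gene_id)
    return OperonTable(table)


def load_ppi(world_dir: str) -> PPIList:
    df = read_tsv(os.path.join(world_dir, "ppi.tsv"),
                  columns=["gene_a", "gene_b"])
    return PPIList([(r.gene_a, r.gene_b) for r in df.itertuples(index=False)])


def load_profiles(world_dir: str) -> pd.DataFrame:
    df = read_tsv(os.path.join(world_dir, "profiles.tsv"))
    df = df.set_index(df.columns[0])
    return df.astype(int)


def load_architectures(world_dir: str) -> dict[str, DomainArchitecture]:
    df = read_tsv(os.path.join(world_dir, "domains.tsv"),
                  columns=["gene", "accession", "start", "end"])
    out: dict[str, DomainArchitecture] = {}
    for gene, sub in df.groupby("gene", sort=True):
        doms = list(sub["accession"])
        coords = [(int(s), int(e)) for s, e in zip(sub["start"], sub["end"])]
        out[gene] = DomainArchitecture(gene, doms, coords)
    return out


def load_expression(world_dir: str) -> pd.Series:
    df = read_tsv(os.path.join(world_dir, "expression.tsv"),
                  columns=["gene", "fold_change"])
    return pd.Series([float(x) for x in df["fold_change"]],
                     index=list(df["gene"]))


def load_pathways(world_dir: str) -> pd.DataFrame:
    return read_tsv(os.path.join(world_dir, "pathways.tsv"),
                    columns=["gene", "pathway"])


# ---------------------------------------------------------------- running

@dataclass
class RunManifest:
    config_hash: str
    input_checksums: dict[str, str]
    stage_seconds: dict[str, float]
    warnings: list[str]
    version: str = __version__

    def write(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class PipelineResult:
    initial_model: NetworkModel
    model: NetworkModel
    expansion_report: object
    da_validation: object
    validation: object
    enrichment: pd.DataFrame
    manifest: RunManifest


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def model_to_channel_frame(model: NetworkModel,
                           de_calls: dict[str, str] | None = None,
                           ) -> pd.DataFrame:
    """Model as one row per gene with an 'X' column per evidence channel."""
    rows = []
    for rec in model.records():
        row = {
            "gene": rec.gene, "role": rec.role, "organism": rec.organism,
            "source_gene": rec.source_gene,
            "template": "X" if "template" in rec.evidence else "",
        }
        for ch in ALL_CHANNELS:
            row[ch] = "X" if ch in rec.evidence else ""
        row["de"] = (de_calls or {}).get(rec.gene, "")
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", "role", "organism",
                                       "source_gene", "template",
                                       *ALL_CHANNELS, "de"])


def export_network(model: NetworkModel, output_prefix: str,
                   de_calls: dict[str, str] | None = None) -> list[str]:
    """Write a SIF-style edge list and a node attribute table.

    Each evidence tag with a recorded anchor becomes one edge
    (gene, evidence-type, anchor); template assignments link the gene to
    its source template gene. The node table carries the fold-change class
    (up/down/none) for colour-coding in external viewers.
    """
    if len(model) == 0:
        raise DataError("cannot export an empty model")
    edges = []
    for rec in model.records():
        if "template" in rec.evidence and rec.source_gene:
            edges.append((rec.gene, "template", rec.source_gene))
        for ch, anchor in sorted(rec.anchors.items()):
            edges.append((rec.gene, ch, anchor))
    edge_path = output_prefix + ".edges.sif"
    with open(edge_path, "w", encoding="utf-8") as fh:
        for g, ch, anchor in edges:
            fh.write(f"{g}\t{ch}\t{anchor}\n")
    node_path = output_prefix + ".nodes.tsv"
    nodes = pd.DataFrame(
        [{"gene": rec.gene,
          "evidence": ",".join(sorted(rec.evidence)),
          "role": rec.role,
          "de_class": (de_calls or {}).get(rec.gene, "")}
         for rec in model.records()],
        columns=["gene", "evidence", "role", "de_class"])
    write_tsv(nodes, node_path)
    return [edge_path, node_path]


def run(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; write all artifacts under ``config.output_dir``."""
    os.makedirs(config.output_dir, exist_ok=True)
    timings: dict[str, float] = {}
    warnings_log: list[str] = []

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 4)
        return _T()

    wd = config.world_dir
    with stage("load"):
        templates = load_templates(wd)
        operons = load_operons(wd)
        profiles = load_profiles(wd)
        ppi = load_ppi(wd)
        regulon, regulon_hits = load_regulon(wd)
        architectures = load_architectures(wd)
        expression = load_expression(wd)
        pathways = load_pathways(wd)
        hits = {org: load_hits(wd, org) for org in templates}

    with stage("map"):
        mappings = [map_template(templates[org], hits[org], operons,
                                 config.thresholds)
                    for org in sorted(templates)]
        initial = merge_mappings(mappings, config.thresholds)
        warnings_log += initial.warnings

    with stage("expand"):
        channels = {}
        if "operon" in config.enabled_channels:
            channels["operon"] = recruit_by_operon(initial, operons)
        if "ppi" in config.enabled_channels:
            channels["ppi"] = recruit_by_ppi(initial, ppi)
        if "regulon" in config.enabled_channels:
            channels["regulon"] = map_regulon(regulon, regulon_hits,
                                              config.thresholds)
        if "profile" in config.enabled_channels:
            rec = recruit_by_profile(initial, profiles,
                                     params=config.relatedness)
            for g in rec.skipped_model_genes:
                warnings_log.append(f"model gene {g} lacks a profile; skipped")
            channels["profile"] = [Recruit(r.gene, "profile", r.anchor,
                                           r.score)
                                   for r in rec.recruits]
        model, exp_report = merge_evidence(initial, channels)
        warnings_log += exp_report.notes

    with stage("validate_da"):
        da_section = validate_model_pairs(initial, architectures,
                                          config.da_threshold,
                                          config.da_weights)
        for src, tgt in da_section.skipped:
            warnings_log.append(f"no architecture for pair {src}->{tgt}")

    with stage("validate_expression"):
        de_calls = call_de(expression, config.de_params)
        report = validate_channels(model, de_calls, N=len(expression))

    with stage("enrich"):
        enrichment = pathway_enrichment(model.members, pathways,
                                        expression.index,
                                        alpha=config.enrichment_alpha)

    with stage("write"):
        out = config.output_dir
        write_tsv(initial.to_frame(), os.path.join(out, "initial_model.tsv"))
        write_tsv(model_to_channel_frame(model, de_calls),
                  os.path.join(out, "expanded_model.tsv"))
        write_tsv(da_section.to_frame(), os.path.join(out, "da_validation.tsv"))
        write_tsv(report.to_frame(), os.path.join(out, "validation.tsv"))
        enr = enrichment.copy()
        if not enr.empty:
            enr["p_value"] = enr["p_value"].map(lambda p: f"{p:.3g}")
            enr["bh_adjusted"] = enr["bh_adjusted"].map(lambda p: f"{p:.3g}")
            enr["enriched"] = enr["enriched"].map(lambda b: "X" if b else "")
        write_tsv(enr, os.path.join(out, "enrichment.tsv"))
        export_network(model, os.path.join(out, "network"), de_calls)
        summary = _summary_text(initial, exp_report, da_section, report,
                                enrichment)
        with open(os.path.join(out, "summary.txt"), "w",
                  encoding="utf-8") as fh:
            fh.write(summary)

    cfg_hash = hashlib.sha256(
        json.dumps(config.canonical(), sort_keys=True).encode()).hexdigest()
    checksums = {
        os.path.basename(p): _sha256(p)
        for p in sorted(glob.glob(os.path.join(wd, "*.tsv")))
    }
    manifest = RunManifest(cfg_hash, checksums, timings, warnings_log)
    manifest.write(os.path.join(config.output_dir, "manifest.json"))
    return PipelineResult(initial, model, exp_report, da_section, report,
                          enrichment, manifest)


def _summary_text(initial, exp_report, da_section, report, enrichment) -> str:
    lines = [
        "network prediction summary",
        "==========================",
        f"initial model genes: {len(initial)}",
    ]
    for ch in ALL_CHANNELS:
        if ch in exp_report.channel_new:
            lines.append(
                f"recruited via {ch}: {exp_report.channel_new[ch]} new, "
                f"{exp_report.channel_corroborated[ch]} corroborated")
    lines.append(f"new genes (union): {exp_report.n_new_union}")
    lines.append(f"expanded model genes: {exp_report.n_expanded}")
    lines.append(
        f"domain-architecture pairs: {da_section.n_conserved} conserved, "
        f"{da_section.n_flagged} flagged (threshold {da_section.threshold})")
    lines.append(f"genome size N={report.N}, DE genes A={report.A}")
    for row in report.rows:
        lines.append(
            f"  {row.channel:9s} K={row.K:4d} V={row.V:3d} "
            f"P={row.p_value:.3g}")
    n_enr = int(enrichment["enriched"].sum()) if not enrichment.empty else 0
    lines.append(f"enriched pathways (P <= 0.05): {n_enr}")
    return "\n".join(lines) + "\n"
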