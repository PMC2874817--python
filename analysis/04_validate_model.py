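#!/usr/bin/env python
"""Validate the predicted network: domain architectures and expression.

Scores every template-mapped gene pair for domain-architecture
conservation (flagging pairs below 0.9 with the offending accessions),
calls differential expression from the fold-change table, and computes
the per-channel hypergeometric validation table. Writes
results/da_validation.tsv and results/validation.tsv.
"""

import argparse
import os

from osmonet.domain_architecture import validate_model_pairs
from osmonet.expansion import (
    Recruit,
    map_regulon,
    merge_evidence,
    recruit_by_operon,
    recruit_by_ppi,
)
from osmonet.io import write_tsv
from osmonet.phylo_profiles import recruit_by_profile
from osmonet.pipeline import (
    load_architectures,
    load_expression,
    load_hits,
    load_operons,
    load_ppi,
    load_profiles,
    load_regulon,
    load_templates,
)
from osmonet.template_mapping import (
    MappingThresholds,
    map_template,
    merge_mappings,
)
from osmonet.validation_stats import call_de, validate_channels


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--world", default="results/world")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    thr = MappingThresholds()
    templates = load_templates(args.world)
    operons = load_operons(args.world)
    mappings = [map_template(templates[org], load_hits(args.world, org),
                             operons, thr)
                for org in sorted(templates)]
    initial = merge_mappings(mappings, thr)

    regulon, regulon_hits = load_regulon(args.world)
    channels = {
        "operon": recruit_by_operon(initial, operons),
        "ppi": recruit_by_ppi(initial, load_ppi(args.world)),
        "regulon": map_regulon(regulon, regulon_hits, thr),
    }
    rec = recruit_by_profile(initial, load_profiles(args.world))
    channels["profile"] = [Recruit(r.gene, "profile", r.anchor, r.score)
                           for r in rec.recruits]
    model, _ = merge_evidence(initial, channels)

    da = validate_model_pairs(initial, load_architectures(args.world))
    expr = load_expression(args.world)
    de_calls = call_de(expr)
    report = validate_channels(model, de_calls, N=len(expr))

    os.makedirs(args.out, exist_ok=True)
    write_tsv(da.to_frame(), os.path.join(args.out, "da_validation.tsv"))
    write_tsv(report.to_frame(), os.path.join(args.out, "validation.tsv"))

    print(f"domain architectures: {da.n_conserved} pairs conserved, "
          f"{da.n_flagged} flagged below {da.threshold}")
    for p in da.pairs:
        if p.flagged:
            detail = ",".join(p.missing_in_target + p.copy_count_diffs) \
                or ",".join(p.extra_in_target)
            print(f"  flagged {p.source_gene}->{p.target_gene} "
                  f"score={p.score:.2f} ({detail})")
    print(f"genome N={report.N}, DE genes A={report.A}")
    for row in report.rows:
        print(f"  {row.channel:9s} K={row.K:4d} V={row.V:3d} "
              f"P={row.p_value:.3g}")


if __name__ == "__main__":
    main()
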