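#!/usr/bin/env python
"""Expand the initial model over the four guilt-by-association channels.

Recruits genes by operon co-membership, interaction adjacency, regulon
orthology transfer and phylogenetic-profile similarity, merges all
channels, and reports per-channel counts plus how many profile recruits
land in their anchor's planted module. Writes the expanded model to
results/expanded_model.tsv.
"""

import argparse
import os

from osmonet.expansion import (
    Recruit,
    map_regulon,
    merge_evidence,
    recruit_by_operon,
    recruit_by_ppi,
)
from osmonet.io import read_tsv, write_tsv
from osmonet.phylo_profiles import recruit_by_profile
from osmonet.pipeline import (
    load_hits,
    load_operons,
    load_ppi,
    load_profiles,
    load_regulon,
    load_templates,
    model_to_channel_frame,
)
from osmonet.template_mapping import (
    MappingThresholds,
    map_template,
    merge_mappings,
)


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
    model, report = merge_evidence(initial, channels)

    truth = read_tsv(os.path.join(args.world, "truth_modules.tsv"))
    gene_module = dict(zip(truth["gene"], truth["module"]))
    by_gene: dict[str, list[str]] = {}
    for r in rec.recruits:
        by_gene.setdefault(r.gene, []).append(r.anchor)
    pure = sum(1 for g, anchors in by_gene.items()
               if any(gene_module.get(g) is not None
                      and gene_module.get(g) == gene_module.get(a)
                      for a in anchors))

    os.makedirs(args.out, exist_ok=True)
    write_tsv(model_to_channel_frame(model),
              os.path.join(args.out, "expanded_model.tsv"))
    print(f"initial model: {report.n_initial} genes")
    for ch in ("operon", "ppi", "regulon", "profile"):
        print(f"  {ch}: {report.channel_new[ch]} new, "
              f"{report.channel_corroborated[ch]} corroborated")
    print(f"new genes (union): {report.n_new_union}; "
          f"expanded model: {report.n_expanded} genes")
    if by_gene:
        print(f"profile recruits sharing their anchor's planted module: "
              f"{pure}/{len(by_gene)} ({pure / len(by_gene):.0%})")


if __name__ == "__main__":
    main()
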