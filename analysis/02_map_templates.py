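#!/usr/bin/env python
"""Map the template networks onto the target genome and score recall.

Consumes the world directory from 01_simulate_world.py, runs best-hit
mapping at the tool-specific E-value thresholds with the operon tiebreak,
merges the per-organism mappings by evolutionary priority, and compares
the result against the planted ortholog pairs. Writes the initial model
to results/initial_model.tsv.
"""

import argparse
import os

from osmonet.io import read_tsv, write_tsv
from osmonet.pipeline import load_hits, load_operons, load_templates
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
    mappings = []
    for org in sorted(templates):
        m = map_template(templates[org], load_hits(args.world, org),
                         operons, thr)
        mappings.append(m)
        print(f"  {org}: {len(m)} of {len(templates[org].entries)} "
              f"template genes mapped")
    model = merge_mappings(mappings, thr)

    truth_path = os.path.join(args.world, "truth_orthologs.tsv")
    truth = read_tsv(truth_path)
    truth_pairs = {(r.organism, r.template_gene, r.target_gene)
                   for r in truth.itertuples(index=False)}
    found = {(m.organism, p.template_gene, p.target_gene)
             for m in mappings for p in m.pairs}
    recall = len(found & truth_pairs) / len(truth_pairs)

    os.makedirs(args.out, exist_ok=True)
    write_tsv(model.to_frame(), os.path.join(args.out, "initial_model.tsv"))
    print(f"initial model: {len(model)} genes "
          f"(recall vs planted orthologs: {recall:.3f})")
    if model.warnings:
        print(f"  {len(model.warnings)} merge warnings")


if __name__ == "__main__":
    main()
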