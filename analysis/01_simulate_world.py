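#!/usr/bin/env python
"""Generate the synthetic study world and write its input tables.

Builds a desk-scale world (300 target genes, 60 reference genomes) with
planted functional modules, ortholog pairs, an enriched pathway and
differentially expressed genes, and serializes every pipeline input under
results/world/. Prints the planted ground-truth inventory.
"""

import argparse

from osmonet.synthetic_world import build_world, scaled_down_config


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/world")
    args = ap.parse_args()

    world = build_world(scaled_down_config(seed=args.seed))
    world.write(args.out)

    n_pairs = sum(len(p) for p in world.true_pairs.values())
    print(f"world written to {args.out}")
    print(f"  target genes:        {len(world.genes)}")
    print(f"  reference genomes:   {len(world.genomes)}")
    print(f"  planted modules:     {len(world.modules)} "
          f"({len(world.module_genes)} genes)")
    print(f"  true ortholog pairs: {n_pairs} across "
          f"{len(world.templates)} template organisms")
    print(f"  operons:             {len(world.operons)}")
    print(f"  interactions:        {len(world.ppi)}")
    print(f"  regulon members:     {len(world.regulon.members)} "
          f"({len(world.regulon_true_targets)} with target orthologs)")
    print(f"  DE genes:            {len(world.de_genes)}")
    print(f"  planted pathway:     {world.planted_pathway}")


if __name__ == "__main__":
    main()
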