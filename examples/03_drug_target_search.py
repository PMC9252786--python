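"""Rank putative drug targets around a seed module with three algorithms.

TrustRank diffuses outward from the seeds; the multi-level Steiner tree
and the KeyPathwayMiner-style extractor connect the seeds through
intermediate genes (aggregation).  Ranked tables contrast each score
with the gene's interactome degree: low degree + high score suggests a
disease-specific target rather than a generic hub.
"""

from drugnet import (
    gene_graph,
    generate_interactome,
    keypathwayminer_greedy,
    multi_steiner,
    plant_module,
    rank_targets,
    seeds_from_drivers,
    trustrank,
)
from drugnet.synthetic import CANCER_TYPE, DRIVER_CATALOG

base = generate_interactome(n_genes=300, mean_degree=4.0, rng_seed=2)
inter, truth = plant_module(base, module_size=20, n_seeds=6, planted_targets=5,
                            n_decoys=10, rng_seed=2)
seeds = seeds_from_drivers(inter, CANCER_TYPE, {DRIVER_CATALOG})
G = gene_graph(inter)

ranked = rank_targets(trustrank(G, seeds), inter, top_n=5)
print("TrustRank top 5 new targets (seeds excluded):")
print(ranked.rows[["node_id", "normalized_score", "degree"]].to_string(index=False))
in_module = [n for n in ranked.node_ids() if n in truth.module_genes]
print(f"-> {len(in_module)}/5 of the top targets lie in the planted disease module.")

tree = multi_steiner(G, seeds, rng_seed=0)
print(f"\nSteiner union: {len(tree.nodes)} genes, {len(tree.edges)} edges, "
      f"best tree cost {tree.cost:.0f} (connects all {len(seeds)} seeds).")

kpm = keypathwayminer_greedy(G, seeds, k=2)
print(f"KeyPathwayMiner (k=2): {len(kpm.nodes & seeds.genes)} seeds connected "
      f"using {len(kpm.nodes - seeds.genes)} exception gene(s).")
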