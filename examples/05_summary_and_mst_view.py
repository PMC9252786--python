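"""Merge several task results into one network and declutter it with an MST.

Running the same seed set through different algorithms gives partially
overlapping answers; the summary network unions them and counts in how
many tasks each node occurred (high count = robust candidate).  The MST
view connects any node selection through a minimum spanning tree over
shortest-path distances, the same reduction used to keep large networks
readable.
"""

from drugnet import (
    degree_to_seeds,
    gene_graph,
    generate_interactome,
    harmonic_to_seeds,
    mst_view,
    plant_module,
    rank_targets,
    seeds_from_drivers,
    summarize_tasks,
    trustrank,
)
from drugnet.synthetic import CANCER_TYPE, DRIVER_CATALOG

base = generate_interactome(n_genes=300, mean_degree=4.0, rng_seed=4)
inter, truth = plant_module(base, module_size=20, n_seeds=6, planted_targets=5,
                            n_decoys=10, rng_seed=4)
seeds = seeds_from_drivers(inter, CANCER_TYPE, {DRIVER_CATALOG})
G = gene_graph(inter)

tasks = [rank_targets(algo(G, seeds), inter, top_n=10)
         for algo in (trustrank, degree_to_seeds, harmonic_to_seeds)]
summary = summarize_tasks(tasks, inter)
counts = sorted(summary.counts.items(), key=lambda kv: -kv[1])[:5]
print(f"summary over {summary.n_tasks} tasks: {summary.graph.number_of_nodes()} nodes")
print("most recurrent candidates (node, #tasks):", counts)

view = mst_view(G, set(seeds.genes))
connectors = view.nodes - set(seeds.genes)
print(f"\nMST view of the {len(seeds)} seeds: {len(view.edges)} edges, "
      f"{len(connectors)} connector gene(s) added to link them")
print("-> a node appearing in all tasks is a robust target; connectors show"
      " how the seeds hang together in the interactome.")
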