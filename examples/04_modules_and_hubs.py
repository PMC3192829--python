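"""Full reconstruction: network, fast-greedy modules, hubs, interactions.

Runs the study-scale preset end to end, scores the recovered partition
against the planted truth, and exports the standard artifact set (edge
list, node attributes, SIF, GML, machine-readable report).
"""

import glyconet as g
import glyconet.reporting as rep

result = g.run_synthetic_pipeline(g.study_preset(seed=1))

net, part = result.network, result.partition
print(f"selected cutoff tau = {result.scan.selected_tau}")
print(f"network: {net.n_nodes} genes ({rep.percent(net.n_nodes, 2322)}% of the genome), "
      f"{net.n_edges} links")
print(f"modules (>= 5 genes): {part.n_modules}, Q = {part.modularity_q:.3f}")
print(f"module sizes: {part.module_sizes()}")

ari, recovered = g.partition_quality(part, result.truth)
print(f"agreement with planted modules: ARI = {ari:.2f}, "
      f"{100 * recovered:.0f}% of planted members in a reported module")

print(f"standalone modules: {len(rep.standalone_modules(result.inter_links))}"
      f" of {part.n_modules}")

print("\ntop 5 hub genes (gene, links):")
for gid, deg in result.hub_table[:5]:
    print(f"  {gid}\t{deg}")

seed_gene = result.hub_table[0][0]
neighborhood = g.first_neighbors(net, [seed_gene])
print(f"\nfirst-neighbor subnetwork of {seed_gene}: "
      f"{neighborhood.n_nodes} genes, {neighborhood.n_edges} links")

paths = g.export_run(result, "example_output/run")
print("\nexported:", ", ".join(str(p) for p in paths.values()))
# ARI = 1 means the greedy partition reproduces the planted modules
# exactly; standalone modules have no link to any other module, mirroring
# the structural separation of the substrate-specific machineries.
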