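"""Module detection and Zi-Pi keystone-role classification.

Fast-greedy modularity splits the co-occurrence network into modules; each
node is then placed in the Zi (within-module degree z-score) vs Pi
(participation coefficient) plane.  Nodes with Zi > 2.5 are module hubs,
nodes with Pi > 0.62 are connectors between modules — the candidate keystone
taxa of the community.
"""

import bloomnet as bn
from bloomnet.pipeline import PipelineConfig, run_network_stage

community = bn.generate_planted_community()
*_, net = run_network_stage(community.counts, PipelineConfig())

net.partition, q = bn.fast_greedy_partition(net)
summary = bn.topology_summary(net)
print(f"network: {summary.n_nodes} nodes, {summary.n_links} links, "
      f"avgK={summary.avg_k:.2f}, GD={summary.gd:.2f}, avgCC={summary.avg_cc:.2f}")
print(f"modularity Q={q:.3f} with {summary.n_modules} modules")

null = bn.null_distribution(net, 25, seed=0)
print(f"degree-preserving null: Q = {null.modularity_mean:.3f} ± {null.modularity_sd:.3f}"
      f"  (empirical Q is {(q - null.modularity_mean) / null.modularity_sd:.0f} sd above)")

roles = bn.classify_roles(bn.zi_pi(net))
hubs = [r for r in roles if "hub" in r.role]
connectors = [r for r in roles if r.role == "connector"]
print(f"\nmodule hubs (Zi > 2.5): {len(hubs)}")
for r in sorted(hubs, key=lambda r: -r.zi)[:5]:
    print(f"  {r.otu_id}: Zi={r.zi:.2f}, Pi={r.pi:.2f}, degree={r.degree}, "
          f"module {r.module_id}")
print(f"connectors (Pi > 0.62): {len(connectors)}")

ego = bn.ego_subnetwork(net, community.focal_otu) if community.focal_otu in net.graph \
    else None
if ego:
    print(f"\nfocal bloom taxon {ego.focal}: {ego.n_positive} positive / "
          f"{ego.n_negative} negative neighbors")
print("\nModularity far above the degree-preserving null is the signature of real")
print("community structure.  The planted modules are near-cliques, so every")
print("member has the same within-module degree and no node clears the Zi hub")
print("cutoff — field networks, with their sparser and more uneven modules, are")
print("where module hubs and connectors appear.")
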