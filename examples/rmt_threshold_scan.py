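"""Automatic correlation-threshold selection by random matrix theory.

A planted community with five correlated OTU modules is generated, Pearson
correlations are computed on CLR-transformed counts, and the threshold scan
watches the nearest-neighbor spacing distribution (NNSD) of the thresholded
matrix's eigenvalues: Gaussian-ensemble statistics mean correlated noise
still dominates, Poisson statistics mean only modular structure remains.
The selected cutoff is the lowest threshold where the spectrum turns (and
stays) Poisson.
"""

import bloomnet as bn
from bloomnet.pipeline import PipelineConfig, run_network_stage

community = bn.generate_planted_community()          # 300 OTUs, 12 samples
filtered, corr, scan, threshold, net = run_network_stage(
    community.counts, PipelineConfig())

print("threshold  nodes  p(NNSD=Poisson)")
for cand in scan.candidates[40::3]:                  # show the upper grid
    flag = "  <-- Poisson" if cand.is_poisson else ""
    print(f"   {cand.threshold:.2f}    {cand.n_nodes:4d}   {cand.p_value:8.4f}{flag}")

print(f"\nselected threshold: {threshold}")
print(f"network: {net.n_nodes} nodes, {net.n_links} links")
same = sum(1 for u, v in net.graph.edges
           if community.partition[u] == community.partition[v]
           and community.partition[u] != bn.BACKGROUND_MODULE)
print(f"edges inside planted modules: {same}/{net.n_links} "
      f"({100 * same / net.n_links:.1f}%)")
print("\nThe scan lands just above the strongest noise correlations, so almost")
print("every retained edge is a genuine planted co-occurrence.")
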