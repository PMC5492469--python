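"""Comparing two community fractions: PERMANOVA, MRPP and per-taxon tests.

Two planted communities stand in for two filtration fractions sampled on the
same grid.  Whole-community structure is compared on the pooled Bray-Curtis
matrix (Adonis pseudo-F / R^2 and MRPP delta / A with permutation p-values),
and per-taxon Welch tests count which taxa shift between fractions.
"""

import dataclasses

import bloomnet as bn
from bloomnet.pipeline import PipelineConfig, compare_fractions
from bloomnet.synthetic import CommunityParams

params = CommunityParams(n_otus=150, n_modules=3, module_size=25)
frac_a = bn.generate_planted_community(dataclasses.replace(params, seed=1))
frac_b = bn.generate_planted_community(dataclasses.replace(params, seed=2))

config = PipelineConfig(n_null=10, n_permutations=199, seed=0,
                        outdir="scratch_compare_out")
result = compare_fractions(frac_a.counts, frac_b.counts, config, labels=("PA", "FL"))

for label in ("PA", "FL"):
    r = result[label]
    print(f"{label}: threshold={r['threshold']:.2f}, {r['n_nodes']} nodes, "
          f"{r['n_links']} links, Q={r['modularity']:.3f}")
print(f"\nAdonis: pseudo-F={result['adonis']['pseudo_F']:.2f}, "
      f"R2={result['adonis']['R2']:.3f}, p={result['adonis']['p']:.4f}")
print(f"MRPP:   delta={result['mrpp']['delta']:.3f}, "
      f"A={result['mrpp']['A']:.3f}, p={result['mrpp']['p']:.4f}")
print(f"taxa significantly higher in PA: {result['taxa_higher_in_A']}, "
      f"lower: {result['taxa_lower_in_A']}")
print("\nIndependently generated fractions separate cleanly (high R2, low p),")
print("the same contrast used to show that attached and free-living bacteria")
print("form distinct communities.")
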