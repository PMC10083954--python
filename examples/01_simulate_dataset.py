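"""Generate a synthetic study dataset and look at its structure.

The generator emulates a dioecious-plant sex-chromosome study: a genetic
cross (father, mother, 20 sons, 32 daughters), wild accessions of two
sister species plus a third relative, and an outgroup, over 57 genes in
three regimes around a shifted PAR boundary.
"""

from collections import Counter

from parshift import SimulationConfig, emit_dataset

config = SimulationConfig()
dataset = emit_dataset(config, seed=1, outdir="example_dataset")

print(f"genes: {len(dataset.tables)}  samples: {len(dataset.samples)}")
print("regimes:", dict(Counter(dataset.truth.regimes.values())))
sites = [t.n_sites for t in dataset.tables]
print(f"segregating sites per gene: min {min(sites)}, mean {sum(sites)/len(sites):.0f}, max {max(sites)}")
print("true boundaries at gene indices:",
      dataset.truth.boundary_a_cut, "(species A) /", dataset.truth.boundary_b_cut, "(species B)")
# The 'left' genes recombine in every species (pseudoautosomal), 'mid'
# genes are sex-linked only in species A (the recent NRY expansion), and
# 'right' genes are anciently sex-linked in all three dioecious species.
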