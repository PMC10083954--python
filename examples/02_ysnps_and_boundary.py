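"""Call Y-linked SNPs from the cross, screen them in wild samples, and
locate each species' PAR boundary by changepoint inference."""

from parshift import SimulationConfig, simulate_dataset
from parshift.boundary import assign_regions
from parshift.pipeline import RunConfig, ysnp_stage

dataset = simulate_dataset(SimulationConfig(), seed=1, with_fragments=False, with_counts=False)
run = RunConfig(seed=1, n_boot=500)
calls, table, summary = ysnp_stage(dataset.tables, dataset.samples, dataset.annotations, run)

print(summary[["map_pos_cM", "n_cross", "A_lenient", "B_lenient", "shared_ancient", "A_specific"]]
      .to_string(max_rows=12))

regions = assign_regions(
    (summary["A_lenient"] >= 1).to_numpy(),
    (summary["B_lenient"] >= 1).to_numpy(),
    dataset.annotations, n_boot=500, seed=1,
)
a, b = regions.boundary_a, regions.boundary_b
print(f"\nspecies A boundary before gene index {a.cut} (LRT {a.lrt:.1f}, CI [{a.ci_low}, {a.ci_high}])")
print(f"species B boundary before gene index {b.cut} (LRT {b.lrt:.1f}, CI [{b.ci_low}, {b.ci_high}])")
print("truth:", dataset.truth.boundary_a_cut, "/", dataset.truth.boundary_b_cut)
# Genes between the two cuts form the 'mid' region: male-specific SNPs in
# species A but not B, i.e. the recent expansion of the non-recombining Y.
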