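"""Map cellular phenotypes onto niches and interfaces.

Plants two marker-context dependences in a synthetic tissue (a CD4-T
marker rising with the TLS niche weight and a macrophage marker rising
at the cancer x inflammatory interface), runs the association pipeline
(Spearman rho, joint FDR, eligibility rules) and prints the pruned
architecture table.
"""

from nichescape import (
    NicheBank,
    PlantedMarker,
    associations,
    cell_niche_weights,
    default_niche_bank,
    fdr_filter,
    init_field,
    simulate_tissue,
    summarize_architecture,
    synth_cells_from_field,
)

b0 = default_niche_bank()
bank = NicheBank(b0.B * 8, b0.cell_types, b0.niche_names)
field = simulate_tissue(init_field(4, f=0.25, seed=42))
planted = [
    PlantedMarker("CD4-T", "pSTAT_like", ("niche", 3), slope=1.0, noise_sd=0.1),
    PlantedMarker("Macrophage", "PDL1_like", ("interface", 0, 2), slope=4.0, noise_sd=0.1),
]
cells, truth = synth_cells_from_field(
    field, bank, planted=planted, extra_markers=["noise_marker"], seed=7
)

weights = cell_niche_weights(cells, bank, r=25.0)
assoc = associations(cells, weights)
print(f"tested {len(assoc)} (cell type, marker, context) triplets")

disc = fdr_filter(assoc, q_max=0.01, rho_min=0.3)
arch = summarize_architecture(disc)
print("architecture table (pruned discoveries):")
print(arch.table[["context_label", "cell_type", "marker", "rho", "q"]].to_string(index=False))
# expected: the two planted associations and nothing for the noise
# marker; rho is the Spearman correlation between marker intensity and
# the niche/interface weight across cells of that type
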