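"""Discover niches in a simulated tissue by simplex (archetype) fitting.

Builds a synthetic tissue whose local composition is a convex mixture of
four known niches, samples kernel-composition sites, fits the simplex
and compares the recovered niche compositions with the planted ones.
"""

import numpy as np

from nichescape import (
    default_niche_bank,
    explained_variance_niches,
    fit_niches,
    init_field,
    kmeans_variance,
    recovery_error,
    sample_sites_from_field,
    simulate_tissue,
)

bank = default_niche_bank()
field = simulate_tissue(init_field(4, f=0.25, seed=0))
X, A, centers = sample_sites_from_field(field, bank, n_images=1, seed=0)
print(f"simulated {X.shape[0]} sites x {X.shape[1]} cell types")

model = fit_niches(X, p=4, restarts=10, seed=0)
ev = explained_variance_niches(X, model)
ev_km = kmeans_variance(X, 4, seed=0)
print(f"explained variance: niches {100 * ev:.1f}%  vs  4 k-means clusters {100 * ev_km:.1f}%")
# the simplex model captures the composition continuum (mixtures of
# niches at domain borders), which hard clustering cannot

for j in range(4):
    eps = recovery_error(model.endpoints_celltype, bank.B[:, j])
    print(f"recovery error of planted niche {bank.niche_names[j]!r}: eps = {eps:.2e}")
# eps well below 4.5e-4 means the niche's cell-type density profile was
# recovered essentially exactly (up to niche relabelling)
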