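# nichescape

Niche-phenotype mapping of multiplex histology data.

Multiplex imaging (MIBI, CODEX, in-situ sequencing, …) yields per-cell
tables — positions, cell types, marker intensities — for tissue
sections.  `nichescape` turns such tables into a concise, quantitative
description of tissue architecture for computational biologists and
spatial-omics analysts:

1. **Niche discovery.**  Circular sampling sites of radius *r* (default
   25 μm) are placed uniformly over the tissue and each site's
   cell-type composition is estimated with a Gaussian kernel,
   *g*(**x**, **s**) = exp(−‖**s**−**x**‖²/2r²)/(2πr).  Site
   compositions do not form clusters but a continuum bounded by a
   simplex: after centered, unscaled PCA, archetype analysis fits a
   *p*-vertex simplex in *d* = *p*−1 components.  The vertices are the
   **niches** — recurring histological units with characteristic
   cell-type densities — and each site is a weighted average
   **c** ≈ Σₖ αₖ **b**ₖ with α on the probability simplex.
2. **Segmentation and interfaces.**  Solving **c** = *B*·α (α ≥ 0,
   Σα = 1) by exact constrained least squares for a site centred on
   every cell assigns niche weights to cells; the product αᵢαⱼ scores
   **interfaces** between niches, and the mixing score
   *m* = ⟨α_c(α_t+α_i)⟩/(⟨α_t⟩+⟨α_i⟩) ranks tumor samples from
   compartmentalized to mixed.
3. **Phenotype mapping.**  Spearman correlation between phenotypic
   marker intensity and niche/interface weight, per cell type, with
   joint tail-area FDR control, eligibility rules and redundancy
   pruning, summarised into a tissue **architecture table**.
4. **Tissue simulation and power analysis.**  A reaction-diffusion
   system, dαᵢ/dt = βαᵢ(αᵢ⁴/(αᵢ⁵+K⁵) − 1/2K) + D∇²αᵢ, grows realistic
   contiguous niche domains from random initial conditions; synthetic
   site matrices *X* = *B·A* and cell tables with planted
   niche-phenotype associations support testing and the rare-niche
   power analysis.
5. **Cross-scale analysis.**  Bulk composition is the spatial average
   *C* = *B*θ with θ on the simplex, so inter-patient variation must be
   bounded by the niche simplex; the package maps cell-type
   vocabularies between datasets, checks containment and dissects
   designated endpoints (e.g. healthy tissue) out of bulk samples.

## Worked example

`examples/01_niche_discovery.py` simulates a four-niche tissue, samples
326 sites (one 800×800 μm image at 25 μm radius) and refits the niches:

```
simulated 326 sites x 17 cell types
explained variance: niches 100.0%  vs  4 k-means clusters 83.9%
recovery error of planted niche 'cancer': eps = 4.07e-06
recovery error of planted niche 'fibrotic': eps = 6.36e-07
recovery error of planted niche 'inflammatory': eps = 3.39e-06
recovery error of planted niche 'TLS': eps = 1.64e-05
```

Four archetypes explain the site-composition variance essentially
completely — sites are mixtures of niches, which hard clustering cannot
represent — and every planted niche composition is recovered with RMSE
far below the capture threshold of 4.5×10⁻⁴.
`examples/03_phenotype_mapping.py` then recovers planted
marker-to-niche and marker-to-interface associations:

```
architecture table (pruned discoveries):
      context_label  cell_type     marker      rho            q
                TLS      CD4-T pSTAT_like 0.629621 3.716626e-34
cancerxinflammatory Macrophage  PDL1_like 0.468114 9.906396e-16
```

The other examples cover segmentation/interfaces, the power scan and
the macro-scale analysis.  A thin CLI (`nichescape sites|niches|segment|
phenomap|simulate|power|macro`) wraps the same functions for shell use.

## Documentation

`docs/methods.md` describes the model, its parameters and defaults, the
synthetic-data generator and its limits, numerical choices and known
limitations.
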