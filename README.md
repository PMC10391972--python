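# isomigrate

Stable-isotope assignment to origin and migratory-connectivity analysis
for birds (or any animal) whose metabolically inert tissue — here a
winter-grown feather — records where it was synthesized.

Researchers studying migratory connectivity need to know where the members
of each breeding population spend the non-breeding season.  Feather δ²H
and δ¹³C track continental isotope gradients, so comparing a feather's
values against calibrated isoscapes yields a probability surface of molt
origin.  `isomigrate` implements that workflow end to end:

1. **Isoscape calibration** — environmental surfaces to feather values:
   δ²H_f = 17.57 + 0.95·δ²H_p, plant δ¹³C + 2‰ discrimination, optional
   species-range masking.
2. **Probabilistic assignment** — per-individual bivariate-normal
   likelihood surfaces
   f(y|μ(x), Σ) with Σ = [[σ_H², ρσ_Hσ_C], [ρσ_Hσ_C, σ_C²]], normalized
   over valid cells; binarized with the 2:1 odds rule (the minimal
   highest-probability cell set reaching ≥ 66.7% cumulative mass) and
   stacked per population.  Feathers with δ²H_f < −120‰ (grown on the
   breeding grounds) are filtered first.
3. **Spatial clustering** — Schoener's D similarity (D = 1 − ½Σ|p₁ − p₂|)
   with a cell bootstrap, average-linkage clustering of individuals on
   correlation distances (dendrogram cut at 0.5), geographically weighted
   k-means over the map, and zonal maximum-likelihood allocation of
   individuals to clusters.
4. **Isotopic niche overlap** — maximum-likelihood and Bayesian standard
   ellipses (SEA = π√(λ₁λ₂), SEAc small-sample correction, inverse-Wishart
   posterior draws), pairwise percent overlap of the "40%" (1-SD)
   ellipses, and LDA fusion of three isotopes + wing length into two niche
   axes.
5. **Synthetic worlds** — planar isoscapes, molt regions and populations
   with recorded cell-level truth, so the whole pipeline is testable at
   desk scale without proprietary rasters or field data.

The package is a library: import it from Python, or start from the
narrative scripts in `examples/`.  See `docs/methods.md` for the models,
assumptions and defaults.

## Worked example

`examples/03_cluster_regions.py` simulates a migratory divide — two
50-bird populations molting in disjoint regions ~45‰ apart in feather
δ²H — and runs assignment, similarity, clustering and zonal allocation:

```text
similarity matrix: 96 birds, mean off-diagonal Schoener's D = 0.271
dendrogram cut at 0.5 found 4 individual clusters; spatial k-means used k = 2

share of each population allocated to each spatial cluster:
cluster         1      2
population              
East        1.000  0.000
Pacific     0.188  0.812

zonal membership matches the true molt region for 90.6% of birds
```

Four birds of 100 were removed by the −120‰ outlier filter; each remaining
bird's 2/3-odds region was intersected with the k = 2 spatial cluster map.
`East` birds land entirely in cluster 1 and most `Pacific` birds in
cluster 2 — the divide is recovered, and 90.6% of individuals are
allocated to the cluster covering their true molt region.
`examples/04_niche_overlap.py` completes the picture with niche ellipses:

```text
[strong] Pacific vs East on δ²H–δ¹³C:
  SEAc = 74.3 / 66.9 (‰)², Bayesian SEA median = 70.8 / 63.8 (‰)²
  ellipse overlap = 0.0% of the union (0.0% of the smaller ellipse)
[weak] Manitoba vs Saskatchewan on δ²H–δ¹³C:
  SEAc = 169.2 / 154.2 (‰)², Bayesian SEA median = 160.9 / 147.1 (‰)²
  ellipse overlap = 64.3% of the union (82.1% of the smaller ellipse)
```

Disjoint molt regions produce compact, non-overlapping niches (strong
connectivity); shared regions produce broad ellipses overlapping at 64% —
exactly the contrast the niche-overlap proxy is meant to detect.

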