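"""Derive discrete candidate non-breeding regions from assignment surfaces.

Runs the full pipeline on the "strong" preset: Schoener's-D similarity
among individual surfaces (with a cell bootstrap), hierarchical clustering
of individuals, spatially weighted k-means over the map (k = 2 candidate
regions), and zonal maximum-likelihood allocation of each bird to a
region.  Prints the population × cluster proportion table and the recovery
rate against the simulation truth.
"""

from isomigrate import get_preset, region_recovery_rate, run_pipeline

scenario, _ = get_preset("strong")
res = run_pipeline("strong", k=2, seed=1)

d = res.similarity.values
n = len(res.similarity.ids)
print(f"similarity matrix: {n} birds, mean off-diagonal Schoener's D = "
      f"{(d.sum() - n) / (n * n - n):.3f}")
print(f"dendrogram cut at 0.5 found {max(res.individual_labels.values())} "
      f"individual clusters; spatial k-means used k = {res.cluster_map.k}")

print("\nshare of each population allocated to each spatial cluster:")
print(res.proportions.round(3).to_string())

rate = region_recovery_rate(res, scenario)
print(f"\nzonal membership matches the true molt region for {rate:.1%} of birds")
print("(populations molt in disjoint regions here, so a sharp split between")
print(" clusters indicates the divide was recovered)")
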