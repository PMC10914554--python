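"""Generate a small seeded synthetic study and look at what it contains.

The generator emulates the survey setting: sites along a depth transect,
replicate cores sliced into sub-bottom horizons, specimen counts that decay
with depth and horizon, paired amplicon reads per slice (including a
configurable share of background reads from soft-bodied taxa that are never
counted), and abiotic covariates coupled to the depth/horizon gradient.
"""

from meiobar import SimulationConfig, simulate_study

cfg = SimulationConfig(
    n_sites=2, depths_m=(54, 394), n_species=8, n_background_species=3,
    n_other_species=1, reads_per_slice=120, seed=1,
)
asvs, gt, reads, count_table = simulate_study(cfg, outdir="scratch/example_study")

print(f"reference ASVs:      {len(asvs)} (in {len(gt.species_sequences)} species)")
print(f"slices with reads:   {len(reads)}")
print(f"counted specimens:   {count_table['count'].sum()}")
print(f"taxon groups seen:   {sorted(count_table['taxon_group'].unique())}")
# Counts fall with depth: compare total specimens at the two sites.
per_site = count_table.groupby("site")["count"].sum()
print(f"specimens per site:  {per_site.to_dict()}  (deeper site has fewer)")
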