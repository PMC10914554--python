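# meiobar

Morphology-free meiofaunal metabarcoding analysis: from paired 18S-V4
amplicon reads and sorted-specimen counts to species-proxy community
profiles, count-normalized abundance matrices, Hill-number diversity
estimates, and community/abiotic correlation statistics.

## The problem

Meiofaunal communities (nematodes, copepods, polychaetes and the other small
benthic invertebrates of soft sediments) are ecologically informative but
nearly impossible to identify to species morphologically at survey scale.
`meiobar` implements a taxonomy-free alternative built around three ideas:

1. **ASV-3 species proxies.** Amplicon sequence variants (ASVs) of the
   18S-V4 barcode are compared by p-distance and clustered by group-average
   (UPGMA) linkage; the dendrogram is cut strictly below 3% dissimilarity.
   Each cluster — an *ASV-3* — is treated as a species-compatible unit.
   Merged reads are mapped back to this reference at ≤3% read dissimilarity
   with ≤1% gaps of at most 3 bp per gap, giving one read-count profile per
   sediment slice.
2. **Count normalization.** Read numbers are biased by PCR efficiency and
   rDNA copy number, so per-slice profiles are rescaled to the *counted*
   number of sorted hard-bodied specimens: for cluster *c* with reads
   *r_c*, the estimated count is *r_c / Σr × N*. Reads from sources that
   were never counted (soft-bodied taxa, gut contents, adsorbed DNA) push
   the per-slice counts/ASV-3 index below 1; a single global threshold τ*
   zeroes low-count matrix cells until the index exceeds 1 in every slice.
3. **Community statistics.** Hill numbers ⁰D (richness) and ¹D
   (exp-Shannon) with Chao-type asymptotic estimators, rarefaction /
   extrapolation and bootstrap errors; square-root transformed Bray-Curtis
   similarity, group-average dendrograms and pairwise permutational
   MANOVA; and BIOENV — the exhaustive search for the abiotic-variable
   subset whose Euclidean distances best rank-correlate (Spearman) with
   the community dissimilarities, judged against a permutation-derived
   significance threshold.

A first-class synthetic-study generator (`meiobar.simulate`) emulates the
survey setting — depth transects, replicate cores, the 1,2,2,2,3,3,4 cm
slicing scheme, abundance decaying with depth and sub-bottom horizon, an
8.9% background-read share, and abiotic covariates coupled to the planted
depth/horizon gradient — so every stage is testable offline with known
ground truth.

## Worked example

```python
from meiobar import SimulationConfig, run_synthetic_study

res = run_synthetic_study(SimulationConfig(seed=1), n_perm=49)
```

runs a full default-scale study (6 sites at 54–1418 m, 3 cores each, 7
horizons, ~57k read pairs) through QC → clustering → mapping →
normalization → zeroing → diversity → community statistics. The run prints
(see `examples/06_community_bioenv.py`):

```
BIOENV best subset: ('depth_m', 'horizon_cm')
  Spearman rho = 0.664
  permutation threshold (49 permutations) = 0.239 -> significant

counts/ASV-3 index span after zeroing: 1.14 - 23.61
```

Meaning: the abiotic pair {bottom depth, sub-bottom horizon} — exactly the
planted drivers of the simulated community — correlates best with the
Bray-Curtis structure (ρ = 0.66, well above the max-over-permutations
threshold 0.24), and after background zeroing every slice's counted
specimens exceed its number of surviving species proxies (index > 1), with
the span 1.1–23.6 across slices. The smaller scripts in `examples/`
demonstrate each capability in isolation (simulation, read QC, reference
clustering, normalization/zeroing, diversity estimation).

A thin CLI mirrors the library (`meiobar simulate|qc|buildref|abundance|
diversity|community|abiotics|run-all`); see `meiobar --help`.

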