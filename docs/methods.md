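# Methods

This note records the models, conventions and numerical choices behind
`meiobar`, stage by stage, including the choices that were genuinely open
and why they were made as they were.

## Read QC and pair merging (`meiobar.qc`)

Paired 2×250 bp reads are processed in the order: 3′ quality truncation →
anchored 5′ primer removal → length / N-run filtering → overlap merging.
A failure in either mate rejects the pair.

- **Quality truncation** uses the running-sum rule: with cutoff *q₀*
  (default phred 25), the kept prefix maximises the running sum of
  (q − q₀) accumulated from the 3′ end; ties resolve to the longest
  prefix, so a read whose qualities all meet the cutoff is unchanged.
  This is the documented behaviour of the standard trimming tools; the
  cutoff 25 is the default study condition.
- **Primer removal** is anchored at the very 5′ end, respects IUPAC
  degeneracy (forward `CCGCGGTAATWCCAGCHY`, reverse
  `TTGGCAAATGCYTTCGCAKTHG`), allows ≤1 substitution by default, and no
  indels. A read without an acceptable primer match is rejected.
- **Filtering** rejects reads shorter than 180 bp or containing more than
  3 consecutive Ns (both bounds inclusive on the passing side: a 180 bp
  read with `NNN` passes).
- **Merging** scans every ungapped overlap length between the forward read
  and the reverse-complemented mate (amplicons are ≤445 bp, so the
  exhaustive scan is cheap), scores each as matches − mismatches, requires
  ≥20 bp overlap and ≤10% overlap mismatches, and takes the best score
  (longer overlap on ties). Disagreeing bases are called from the
  higher-quality mate, ties from the forward mate.

## Species-proxy reference (`meiobar.reflib`, `meiobar.cluster`)

- **p-distance**: mismatched positions / comparable positions under a
  global unit-cost alignment (match 0 / mismatch 1 / gap 1, via edlib);
  columns containing a gap or an N are excluded from the denominator.
  Because the optimal unit-cost alignment need not be unique, the argument
  pair is put in lexicographic order before aligning, which makes the
  distance symmetric by construction.
- **Clustering** is pair-count-weighted average linkage (UPGMA): the
  distance between clusters is the arithmetic mean over all cross pairs.
  The dendrogram is cut *strictly below* the 3% threshold — a merge at
  exactly 0.03 does not join clusters. Equal-height merge candidates are
  ordered by the lexicographically smallest member id (then the other
  member), which makes the partition invariant to input order. The
  implementation is a plain O(n³) agglomeration; the test suite checks it
  against scipy's average-linkage on a thousand random instances.
- Sequences shorter than 325 bp are purged before clustering (mis-paired
  or partial barcodes). Library merging trims old entries to the new
  barcode window, collapses exact duplicate sequences (keeping the
  lexicographically smallest id) and re-clusters the pooled set from
  scratch. Cluster taxonomy and functional group are the majority vote of
  the members; the representative is the longest member.
- Annotation splits clusters into *meiofauna* (used for mapping tallies)
  and *other* via a phylum → group table; unmapped phyla default to
  "other" with a warning.

## Read mapping (`meiobar.mapping`)

Merged reads are aligned to every candidate reference ASV on both strands
with edlib in infix (HW) mode — references carry the primer-binding motifs
while QC-merged reads do not, so the read must be allowed to sit inside the
reference. A hit is admissible iff

- mismatches / aligned columns ≤ 3% (denominator excludes gap columns),
- total gap bases / read length ≤ 1%,
- every individual gap ≤ 3 bp,

all inclusive. The read is assigned to the ASV-3 of the minimum-mismatch
admissible ASV; "other" when that ASV is non-meiofaunal; "unmapped"
otherwise. Equal-distance ties between clusters go to the cluster with
more reads so far in the slice, then to the lexicographically smaller
cluster id. A shared 12-mer prefilter limits the candidate set; with ≥180
bp reads and ≤4% total differences a true hit always shares a 12-mer, and
tests assert the prefiltered and exhaustive paths give identical output.

## Normalization and background zeroing (`meiobar.abundance`)

Estimated counts are `reads_c / Σ(meiofaunal reads) × N` with *N* the
slice's counted hard-bodied specimens; the denominator is meiofauna-mapped
reads (the documented choice — off-target reads never enter). Estimates
sum exactly to *N* before zeroing.

The counts/ASV-3 index *N / nnz* must strictly exceed 1 in every populated
slice. The zeroing threshold τ* is the smallest value from {0} ∪ {cell
values} such that zeroing all cells < τ* achieves this; raising τ never
lowers any slice's index while nnz > 0, so τ* is found by binary search
and verified against a brute-force scan in the tests. One *global*
threshold is used (the per-slice variant is available as a sensitivity
flag). Slices with N ≤ 1 can never satisfy the strict index and are zeroed
entirely and flagged. Zeroed mass is not redistributed and surviving cells
are not rescaled by default (`renormalize=True` rescales to the slice
total). Areal abundance divides summed counts by
(cores × core area × thickness), core area π·(0.047 m)² ≈ 6.94×10⁻³ m².

## Diversity (`meiobar.diversity`)

Orders q = 0 (richness) and q = 1 (exp-Shannon). Asymptotic estimators:
Chao1 `S + f1²/(2 f2)` (bias form `S + f1(f1−1)/2` when f2 = 0; no
small-sample (n−1)/n factor) and the singleton-corrected low-bias entropy
estimator for q = 1, exponentiated. Interpolation is exact — the
hypergeometric expectation of richness, and for q = 1 the expectation of
the frequency counts `E[f_k(m)]` plugged into the entropy sum.
Extrapolation: richness approaches the Chao1 asymptote as
`S + f̂0(1−(1−f1/(n f̂0+f1))^(m−n))`; entropy at n+m* is the sample-size
weighted blend `(n H_obs + m* H_est)/(n+m*)`, exponentiated — anchored at
the observed value, monotone, approaching the asymptotic estimate. Points
beyond 2n are flagged unreliable.

Uncertainty comes from B = 200 bootstrap resamples of the coverage-adjusted
community: detected probabilities are deflated to the estimated sample
coverage and f̂0 undetected species share the remainder; the 95% CI is the
percentile interval. For a lower-bound estimator with a right-skewed
bootstrap distribution this interval is conservative — in simulations at
generous sampling depth it covers the true richness essentially always —
so the test suite checks that nominal coverage is not *under*-shot rather
than a two-sided band.

Replicate cores are combined per site × horizon by element-wise summation,
normalized per 1 cm of horizon thickness, and rounded half-to-even to
return to the integer abundances the frequency-count estimators need;
slices where rounding erases a detected species are flagged.

## Community statistics (`meiobar.community`)

Bray-Curtis similarity `100·(1 − Σ|u−v| / Σ(u+v))` on square-root
transformed profiles; all-zero profiles have no defined similarity and are
dropped with a warning. The dendrogram reuses the UPGMA engine on
100 − similarity and exports Newick with half-height branch lengths.

Pairwise tests are one-way permutational MANOVAs: pseudo-F from the
squared dissimilarities, unrestricted label permutation,
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`. No parametric small-sample
correction is applied — the permutation p-value is the defensible core,
and groups of fewer than two members are skipped.

BIOENV z-scores the abiotic columns (zero-variance columns excluded),
enumerates every non-empty subset, computes Euclidean distances and the
Spearman correlation (average ranks on ties) with the biotic
dissimilarities, and reports the best subset per size and overall. The
significance threshold is the strictest reading of a permutation null: the
maximum best-subset ρ over full re-searches on row-permuted abiotic
tables. Shared-ASV percentages between sites default to the Jaccard
convention (|A∩B|/|A∪B|·100); a smaller-set convention is selectable
because the denominator is genuinely ambiguous.

## Abiotics (`meiobar.abiotics`)

Grain-size spectra fold into clay (<4 μm), silt (4–63 μm) and sand
(>63 μm); point spectra classify directly, explicit bins straddling a cut
split pro-rata on log particle size (instrument bin edges are not
standardized). The silt/clay ratio is flagged undefined at zero clay.
Abiotic tables are validated against the slicing scheme (1,2,2,2,3,3,4 cm;
midpoints e.g. 6 cm for 5–7, 8.5 cm for 7–10) and z-scored copies are
appended.

## Synthetic studies (`meiobar.simulate`)

The generator's defaults are the study conditions: 6 sites at
54–1418 m, 3 cores per site, 7 slices to 17 cm, 2×250 bp reads, an 8.9%
background-read share, and a 325–445 bp barcode flanked by the realized
primer motifs. Species richness (40 hard-bodied + 6 soft-bodied background
+ 2 off-target species, 3 ASVs per hard species) and ~400 read pairs per
slice are scaled-down choices that keep a full study tractable on a
laptop while preserving every structural feature the analysis relies on.

- **Sequences**: one random ancestor per species with realized degenerate
  primers at both ends; within-species variants differ by
  ⌊within·L/2⌋ substitutions in the core (pairwise p-distance <
  within-divergence, default 1.5%); between-species separation is checked
  on the emitted sequences and an infeasible configuration raises.
  Indels are off by default (a flag plants one 1–3 bp indel per variant
  to exercise the mapping gap rule).
- **Communities**: Poisson counts with mean
  `baseline_s · exp(−k_d,s·depth) · exp(−k_h,s·horizon midpoint)`;
  per-species rates scatter lognormally (σ = 0.6) around the configured
  decay rates (0.003 /m, 0.2 /cm), which produces the compositional
  turnover along depth and horizon that the community statistics detect.
  Poisson is the simplest count model; nothing in the analysis depends on
  it. Baselines are lognormal (log-mean 3.0, log-sd 1.2).
- **Reads**: each counted specimen contributes a fixed number of reads by
  default (deterministic largest-remainder allocation), so the noiseless
  pipeline recovers slice counts exactly; multinomial allocation is a
  config option. Background reads from the uncounted soft-bodied pool are
  appended so their expected share equals 8.9% of the slice's reads (plus
  a 2% off-target share when other-species are present). Substitution
  errors are i.i.d. per base (default 0.1%); qualities are constant Q38,
  with a degrading-3′-tail option to exercise trimming.
- **Abiotics**: depth and horizon are exact; each other covariate is
  ρ·z(gradient) + √(1−ρ²)·noise with weak default couplings (|ρ| ≤ 0.2)
  rescaled to plausible units, so {depth, horizon} is the planted BIOENV
  answer.
- **Determinism**: all randomness flows from the config seed; FASTQ is
  gzipped with a zeroed timestamp so identical configs give byte-identical
  files.

What the generator does *not* emulate: chimeras, PCR amplification bias,
rDNA copy-number variation, quality-dependent error profiles, or
denoising artifacts. Passing tests therefore demonstrate the correctness
of the analytical machinery on data satisfying its assumptions, not
robustness to those real-data pathologies.

## Degenerate inputs and tie-breaks (summary)

Empty sequences, all-zero abundance vectors, zero-variance abiotic
columns, all-zero community profiles, single-member permutation groups and
slices with counted specimens but no mapped reads all raise or are flagged
explicitly rather than silently propagated. All tie-breaks (clustering
merge order, mapping assignment, merge-overlap score, trimming) are
documented above and deterministic.

## Known limitations

- The p-distance depends on the unit-cost alignment convention; other
  tools' unpublished alignment heuristics may differ in the third decimal
  for highly diverged pairs (immaterial below the 3% cut).
- The q = 1 extrapolation is a pragmatic blend anchored at the observed
  and asymptotic entropies; alternative published forms differ slightly
  in the transition region.
- The BIOENV permutation threshold re-runs the full subset search per
  permutation and is the slowest step at large permutation counts.
- Counts/ASV-3 zeroing assumes background reads are the *small* cells;
  a background species that dominates a slice's reads survives zeroing.
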