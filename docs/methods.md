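# Methods

## The co-response model

The unit of analysis is a soil compartment observed under full irrigation
(FI) and deficit irrigation (DI), three replicates each. For OTU *i* the
response profile is the vector of all DI×FI replicate-pair abundance
ratios, ordered lexicographically (DI1/FI1, DI1/FI2, …, DI3/FI3) — nine
values under the 3+3 design. We read "nine ratios from three DI and three
FI replicates" as the full 3×3 pair grid, because replicate-wise pairing
would give only three values; the fixed pair order is what makes profiles
of different OTUs comparable position by position.

Zeros are replaced by a configurable positive constant (default 1) in
whatever abundance scale is passed. The default pipeline computes relative
abundances on the **full** table first, applies the 4-of-6 prevalence
filter afterwards, and then takes ratios; both choices are configurable
(`relative_before_filter`, `ratio_scale`) and logged because the zero
replacement value is on a count-like scale — with relative abundances a
replaced zero exceeds every true proportion, which inflates zero-cell
ratios. The transformation is kept literal rather than "fixed", and the
replacement constant is an explicit, mandatory part of the configuration.

Two OTUs are joined by an edge when their profiles are more similar
(positive co-response) or more anti-similar (negative) than expected under
independence. Ratio profiles are invariant to OTU-specific level shifts
(an OTU's overall drought response multiplies its whole profile and leaves
correlations unchanged), so edges reflect *shared replicate-to-replicate
response patterns*, not shared mean responses.

## Edge significance

Per pair and measure (Pearson, Spearman, Bray–Curtis, symmetrized KL on
sum-normalized profiles):

- **Permutation null** — one profile is shuffled relative to the other
  (`n_perm` draws, default 1000; an optional renormalization restores the
  column totals of the two-row submatrix after each shuffle, for inputs
  declared compositional — ratio profiles are not column-constrained, so
  this is off by default).
- **Direction** — "associated" when the observed score is on the similar
  side of the null median (above it for correlations, below for
  dissimilarities), "anti-associated" otherwise.
- **p-value** (default `p_method="perm_z"`) — the two-sided empirical tail
  probability while the observed score lies inside the sampled null; when
  it is more extreme than every sampled permutation, a z-score computed on
  a variance-stabilized scale (Fisher's atanh for correlations, log for
  the dissimilarities) extrapolates the tail, floored at the exact
  enumeration limit 1/n! of the n-column permutation space (2.76e-6 at
  n = 9). The stabilized scale matters: correlations are bounded, so a
  plain z on the raw scale saturates near |z| ≈ √(n−1) and can never
  produce the small p-values that genuinely near-perfect profiles deserve,
  while the empirical tail keeps the test calibrated in the bulk
  (measured type-I on independent pairs: 0.044–0.058 at α = 0.05 across
  measures and seeds).
- Two alternatives are provided: `"perm_tail"` (pure tail counting,
  resolution-limited at 1/(n_perm+1)) and `"pooled_z"`, the z-comparison of
  the bootstrap distribution of the observed score against the permutation
  null over the pooled standard deviation. The pooled variant doubles the
  null variance by construction and is therefore deliberately strict
  (measured type-I ≈ 0.006); it also penalizes unstable scores, which is
  why it is kept as an option rather than dropped. The bootstrap
  (`n_boot` joint column resamples) is only computed when a method needs
  it.
- Degenerate (constant) profiles get p = 1 with no direction. The test is
  made exactly symmetric in its two arguments by canonicalizing their
  order before drawing permutations, and every pair has an independent
  random stream keyed on (seed, pair indices), so networks are
  bit-reproducible given the seed and invariant to pair enumeration order.

**Merging.** Measures whose direction matches the majority are combined;
a direction tie or fewer than `min_support` (default 2) agreeing measures
rejects the edge. The combined statistic is Fisher's −2Σln p with Brown's
dependence correction: the covariance of the −2 ln p terms is approximated
by the Kost–McDermott polynomial evaluated at the absolute correlation of
the measures' permutation scores for that same pair (shared permutation
indices across measures make this estimable). Absolute correlation is used
because two-sided p-values depend on score magnitude; this errs
conservative for negatively coupled measure pairs.

**Multiplicity.** Benjamini–Hochberg across all merged pairs at
`alpha_edge` (default 0.05). Testing is exhaustive over pairs by default;
an optional per-measure extreme-quantile pre-filter
(`prefilter_quantile`) bounds permutation work on large tables, in which
case BH runs across the tested pairs only — the pre-selection mirrors how
ensemble co-occurrence tools bound their candidate edge set, and it is off
by default precisely because the candidate count would otherwise become an
undocumented knob that dominates the result.

Nodes exist only through significant edges (no isolated nodes), carry
kingdom/phylum annotations, and export to edge-list TSV and GraphML.

## Summaries, hubs, enrichment

Edge counts are partitioned by endpoint kingdoms
(bacteria–bacteria / fungi–fungi / bacteria–fungi; edges touching an
"other" kingdom count toward totals only) and by sign; each partition's
+/− ratio is rounded **half-up** to two decimals, matching how the
published table's ratios follow from its printed counts (e.g.
5426/1058 = 5.1285 → 5.13); a partition with no negative edges reports
"undefined" rather than a sentinel. Hubs are the floor(1% × nodes)
highest-degree nodes (minimum 1) — floor reproduces the published 8-of-891
and 6-of-648 hub counts — expanded to include every node tied at the
cutoff degree, which reproduces the 59-node tie case. Taxon enrichment is
the hypergeometric upper tail P(X ≥ k) for k of the taxon's K community
members appearing among the n network nodes drawn from the N-OTU
prevalence-filtered community (the only population that provably contains
every node), flagged at p < 0.01; the rank defaults to phylum.

## Diversity stage

Rarefaction subsamples without replacement on the grid increment,
2·increment, …, max_depth with 10 iterations per depth (the surveyed
configurations: 3,900 → 39,000 reads for 16S libraries, 1,400 → 14,000 for
ITS); samples shallower than the standardized depth are excluded with a
warning. Shannon defaults to base 2 (configurable to e; the base only
rescales comparisons). Group comparison pools each sample's final-depth
iterations (3 replicates × 10 iterations = 30 observations per group) into
a Kruskal–Wallis test with Dunn's rank z post hoc (tie-corrected);
compact letters use unadjusted Dunn p-values at α = 0.05, with BH-adjusted
values reported alongside. Beta diversity: Bray–Curtis on rank-aggregated
relative abundances, classical (Gower-centered) PCoA with
negative-eigenvalue axes dropped but eigenvalues reported, and UPGMA with
ultrametric branch lengths and deterministic lexicographic tie-breaking,
exported as Newick. Differential abundance is the equal-variance two-sample
Student's t per taxon ("over-represented in DI" requires p < α and a
higher DI mean); taxa with zero variance in both groups are reported
untestable, never significant.

## The synthetic generator

`generate_paired_design` emulates the study's layout at desk scale:
default 120 bacterial + 30 fungal OTUs (keeping the real survey's
bacteria:fungi imbalance of roughly 15:1 at ~3% of its size), 3+3
replicates, log-normal baselines (log-mean 5.0, log-sd 1.2 ≈ median 150
counts), per-cell dropout of background OTUs at `zero_rate` (default 0.3,
"heavy" zero inflation), and per-replicate biological variability of
log-sd 1.5 on **both** treatment sides plus log-sd 0.2 measurement noise.
OTU-level mean drought responses (log-sd 0.5) shift whole ratio profiles
without inducing correlation.

Planted modules draw their replicate variability from standardized
per-module latent factors (one over DI replicates — the co-response — and
one over FI replicates) weighted by sign × strength, so two members' ratio
profiles share the f_DI[a] − f_FI[b] pattern across the whole pair grid
and `strength` maps directly onto ratio-space correlation: ≈ 0.97 at
strength 1, ≈ 0.78 at 0.9. Standardizing the factor realizations removes
the otherwise-large seed-to-seed variance of a 3-point sample variance.
Negative modules split into two anticorrelated halves, so they plant both
negative (cross-half) and positive (within-half) edges. Module members get
boosted baselines and are exempt from dropout, guaranteeing they survive
the 4-of-6 prevalence filter. Both-sided replicate variability is what
keeps *background* profiles honest: with variation only on the DI side a
nine-ratio profile collapses to ~3 effective degrees of freedom and
independent OTUs correlate spuriously (mean |r| ≈ 0.59); with both sides
active the mean null |r| is ≈ 0.34.

What the generator does **not** emulate: read-level sequencing error and
chimeras, taxon-specific dropout, phylogenetic signal in the taxonomy
(phyla are assigned round-robin), and between-compartment dependence
(compartments are generated independently). Passing tests therefore
demonstrate that the inference machinery recovers the statistical
structure the method assumes, not that real soil data satisfies those
assumptions.

## Recovery and calibration experiments

The quantities quoted in the documentation are computed by
`coresponse.evaluation` (and re-run by `scripts/acceptance.py`):

- **Type-I calibration**: 500 independent uniform(0.1, 10) profile pairs,
  9 columns, n_perm = n_boot = 200; per-measure rejection at α = 0.05.
- **Module recovery**: 20 runs on the default community (one positive and
  one negative 6-OTU module at strength 0.95), n_perm = 200. A module is
  *recovered* when its correctly-signed detected planted edges span at
  least half its members and no planted edge is detected with the wrong
  sign; a run succeeds when every module is recovered. Edge-level
  detection under BH across ~6,500 pairs is intrinsically partial
  (roughly a third to a half of planted edges at this strength): nine
  exchangeable columns cap how much evidence one pair can carry, and more
  permutations do not change that. Detected planted edges, however, carry
  the correct sign essentially always, which is why the module-level
  statement is the one the package stands behind.

Problem sizes (500 pairs, 20 runs, 150 OTUs, 200 permutations) are chosen
so the whole evaluation completes in a few minutes on one CPU while the
binomial noise of the reported rates stays well inside the margins quoted
for them.

## Known limitations

- The ensemble's per-measure p-values are dependent in ways Brown's
  polynomial approximation only partially captures; merged p-values are
  approximate, and BH control is nominal rather than exact.
- With an extreme-quantile pre-filter enabled, BH across the selected
  pairs does not account for the selection step (the same caveat applies
  to any candidate-based co-occurrence tool).
- The zero→1 replacement is a convention, not an imputation model; ratio
  magnitudes of zero cells depend directly on it.
- UPGMA and PCoA are whole-matrix methods; no attempt is made to handle
  missing distances.
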