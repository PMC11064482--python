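# Methods

This note documents the models, algorithms and numerical choices behind
`microclade`, in the spirit of a statistical package's methods appendix.

## Study design model

`StudyDesign` encodes a crossed reciprocal transplant: litter bags carrying
each site's inoculum deployed at every site, in `n_replicates` replicates,
collected at each of `n_timepoints` time points, plus `survey_counts`
native-litter survey samples per site per time point. With the default
shape (5 × 5 × 4 × 3) this gives 300 deployed bags and 100 collected per
time point; `missing_slots` removes individual sequenced samples (the
default pipeline configuration drops one grassland-site, desert-inoculum T3
replicate, leaving 99 transplant metagenomes) without touching deployment
arithmetic. Succession between time points is not modelled; each simulated
time point is independent, and analyses here use the final one.

## Generative model for communities

The simulator draws each sample's 12-clade composition from a Dirichlet
distribution whose concentration vector depends on the sample's *condition*:

- `climate`: the destination site, for transplants and surveys alike;
- `substrate`: every transplant uses the grassland vector (shared litter
  drives convergence), surveys keep their own site's vector;
- `null`: one shared vector for everything.

A Dirichlet mixture is the simplest compositional model with a controllable
between-condition effect size, matching the compositional structure that
Bray-Curtis PERMANOVA operates on. Default concentrations give each site
two dominant clades (α = 6.0; site *i* favours clades 2*i*+1 and 2*i*+2)
over a baseline of α = 0.4, i.e. a mean dominant-pair share of ≈ 0.75 with
realistic replicate-to-replicate scatter — strong site structure of the
kind the transplant readouts are designed to detect. The `null` vector is
flat (α = 1).

What the simulator deliberately does **not** reproduce: temporal
succession, read-depth heterogeneity beyond the decoy fraction, phylogenetic
correlation between clades, or sequence-level error. Passing tests
demonstrate that the analysis chain recovers structure that is present at
the clade-mixture level; they say nothing about upstream alignment quality
on real reads.

## Hit-table simulation

Reads are simulated at the alignment-output boundary (12-column tabular
format); no sequences exist. Per read: a true clade is drawn from the
sample's mixture; hits land on 1–3 reference entries of that clade at a top
identity drawn from the grid {98.0, 98.7, 100.0} (grid values survive a
text round-trip exactly, so ties are exact by construction, as they are in
real tabular output at printed precision). With probability
`ambiguity_rate` (default 0.3, mirroring the observed fraction of reads
whose best hits tie across clades in litter data of this kind) one or two
other clades receive hits at *exactly* the top identity, forcing a
pseudo-clade call. A `decoy_fraction` (default 0.2) of reads instead
produces background-only hits, sub-98 identities, or weak E-values, so the
filter logic is always exercised. Passing hits get E-values of
10^−U(25,60); decoy E-values sit above 1e−20.

The reference database carries 23 marker core genes for each of 2 genomes
per clade plus 40 background proteins: large enough that tie sets are
unconstrained, small enough to be rebuilt on every run.

## Seed discipline

One user-visible seed fans out to per-sample substreams through
`SeedSequence([seed, crc32(stage), crc32(sample_id)])`. Consequences: runs
are reproducible; results are independent of sample order; and enlarging a
design never reshuffles draws of existing samples. Rarefaction (default
seed 1) and the permutation engines use the same scheme, so permutation
p-values are invariant to input row order (samples are canonically sorted
before permutations are drawn).

## Classification rules

- Filters: identity ≥ 98 (inclusive) and E-value < 1e−20 (strict), applied
  before anything else; background entries are then removed.
- Assignment: per-clade maximum identity, global maximum M, tie set T of
  clades attaining M. |T| = 1 → that clade; |T| ≥ 2 → pseudo clade of
  sorted T; no surviving hits → discarded (tracked in diagnostics, never in
  the count table).
- A read whose best overall hit is a background entry but which retains
  marker hits above the filters is assigned from the marker hits —
  background entries act as competitive decoys only. The stricter
  discard-outright behaviour is available via `discard_background_topped`.
- Rare-pseudo-clade collapse pools counts across **all** samples (a
  per-sample threshold would give samples different column sets); the
  threshold is "fewer than 10", so a pseudo clade totalling exactly 10
  survives.
- Identity comparisons are exact at file precision; no epsilon.

## Rarefaction

A single multivariate-hypergeometric draw (subsampling without replacement)
to depth 50 per sample; samples under the depth are dropped into a report.
One draw — not an average over repetitions — matches the convention of the
ecology utilities this step emulates and keeps counts integral. Collapse
happens before rarefaction, so the broad-pseudo bin competes for the
subsample like any other column.

## Distance-based inference

- **Bray-Curtis** is computed from scratch; the triangle inequality is not
  asserted anywhere because Bray-Curtis does not satisfy it in general.
- **PCoA**: eigendecomposition of the Gower matrix; negative eigenvalues
  are reported unchanged (no Lingoes/Cailliez correction). Coordinates
  exist for positive-eigenvalue axes; the imaginary sub-embedding is kept
  separately for PERMDISP.
- **PERMANOVA** uses sequential (Type-I) sums of squares via hat-matrix
  projections of the cumulative dummy-coded model matrices. Degrees of
  freedom come from rank increments, so confounded terms fail loudly with
  the term name. Total SS = tr(G) = Σ_{i<j} D²ᵢⱼ / n. The permutation
  scheme is unrestricted row permutation; p = (1 + #{F* ≥ F}) / (1 + n_perm)
  with ties counted as extreme; `method="exact"` enumerates all n! orderings
  (guarded to n ≤ 9) and reports the plain tail fraction. Verified to agree
  with vegan's `adonis2` (Df/SS/R²/F to machine precision on shared
  fixtures) and to reduce exactly to classical one-way ANOVA F on
  univariate Euclidean data.
- **PERMDISP** embeds with PCoA keeping real and imaginary axes, computes
  each sample's distance to its group centre as √max(0, d₊² − d₋²), and
  applies a one-way F test on those distances with label permutation. The
  group centre is the centroid (mean) by default — it has a closed-form
  geometric oracle — with the spatial median (Weiszfeld iteration, applied
  per sub-embedding) as an option. Distances agree with vegan's
  `betadisper` for both options. The grouping variable is always supplied
  by the caller; the library infers no default grouping.

## Trait projection and PCA

Trait relative abundances per clade are proportions **over the eight
categories** (row-stochastic), which makes the projection
`profile = abundance @ traits` a simplex-to-simplex linear map: profiles
sum to 1 by construction and the projection is linear in the abundance
table. Pseudo clades carry no trait information, so abundances are
re-normalised over the 12 main clades first; samples with zero main-clade
mass are dropped with a report.

The functional PERMANOVA defaults to Euclidean distance on profiles — the
natural metric for same-scale proportions, and the one consistent with the
characteristically tiny sums of squares such analyses report — with
Bray-Curtis exposed as an option. PCA centers but does not scale by
default (the classical `prcomp` convention; all columns share the
proportion scale); scaling is an option. Factor loadings are Pearson
correlations between component scores and original trait columns; a
constant column yields NaN loadings and is listed in `constant_columns`
rather than raising.

## Convergence test

Centroids are per-axis medians (even groups: mean of the central pair) over
the first 2 ordination axes by default — the plotted axes — configurable to
any k or to all axes. Distances are Euclidean in centroid space; summary
statistics are the arithmetic mean and the n−1 standard deviation of the
five per-site distances; the grassland site's own transplant centroid is
included in the comparison against the grassland survey. The test is
descriptive: the hypothesis with the smaller mean distance is reported,
with an explicit `tie` outcome, and no significance test is attached.

## Problem sizes

Defaults were chosen so a full study simulates and analyses in seconds on
one core: 119 samples (99 transplants + 20 surveys) × 300 reads for the
end-to-end pipeline; 150 reads and 99 permutations for the 20-replicate
scenario-recovery batches; 2,000 null datasets of 20 samples at 199
permutations for the calibration experiment (binomial SE ≈ 0.005 on the
rejection rate). The PERMANOVA permutation engine evaluates all permuted
statistics as chunked einsum contractions of the permuted Gower matrix, so
999 permutations at n ≈ 100 cost well under a second.

## Known limitations

- Sequential SS means term order matters in unbalanced designs; the default
  order is site, inoculum, interaction, and callers who want marginal
  (Type-III-like) tests must fit alternative orders themselves.
- The exact permutation method is factorial in n and guarded at n ≤ 9.
- Weiszfeld's iteration for the spatial median is applied separately to the
  real and imaginary sub-embeddings; for strongly non-Euclidean distance
  matrices the resulting median-based dispersions are an approximation
  (the default centroid path is exact).
- The simulator's decoy model covers the three failure modes the filters
  test (background hit, low identity, weak E-value) but not chimeric or
  multi-mapping reads.
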