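# Methods

This note documents the models, conventions and numerical choices behind
psmkit, in the order of the pipeline. It records *why* each default is
what it is and what the synthetic-data validation does and does not
demonstrate about real data.

## Feature tables and trimming

The unit of analysis is a samples × features matrix of nonnegative
intensities with per-feature mass (Da), retention time (min) and
ionization polarity. Intensity 0 is the canonical encoding of "absent":
blank/NA cells are coerced to 0 on read (and counted in the log) because
the presence/absence analyses require a complete matrix. The RT trim
(default 1–21 min) uses **inclusive** bounds on both ends so boundary
peaks are never silently dropped; it is applied per polarity, before
fusion. Tables live on disk as a trio of plain CSV/TSV files so fixtures
stay diffable; writes use 12 significant digits, making read/write
round-trips lossless to at least 10.

## Polarity fusion

A positive feature p and negative feature n are candidate partners iff
`|(mass_p − offset) − mass_n| ≤ mass_tol` and `|rt_p − rt_n| ≤ rt_tol`.

* `mass_offset` default **2.014552 Da** — the physical [M+H]⁺/[M−H]⁻
  difference (two protons). A replication preset (`paper_mode`) uses
  **2.1046 Da**, a published value whose stated rationale ("roughly the
  mass of two protons") matches the physical constant; both are supported
  because which one an existing dataset was processed with matters more
  than which is physically right.
* `mass_tol` = 0.005 Da and `rt_tol` = 0.10 min: typical Orbitrap/UHPLC
  run-to-run reproducibility. No tolerance has a hidden default — they are
  always present in the config so runs are self-documenting.
* Candidates are resolved to a strict one-to-one assignment greedily by
  ascending adjusted-mass difference, then RT difference, then feature id.
  Greedy-with-verification replaces a manual cross-check with a
  deterministic rule; the mutual-consistency invariant (every pair matches
  in both directions, nobody matched twice) is asserted before return.
* Each merged feature keeps the intensity vector of the mode with the
  greater mean intensity across **all** samples, zeros included; a tie
  keeps positive mode (arbitrary but fixed). New feature ids are prefixed
  `both_` / `pos_` / `neg_` so provenance is visible in every downstream
  output.

## Dissimilarities and richness

* **Canberra** (intensity profiles): per pair, the mean of
  `|xᵢ−yᵢ|/(xᵢ+yᵢ)` over components with `xᵢ+yᵢ > 0`. Double zeros carry
  no information about a pair and are excluded; dividing by the count of
  informative components bounds the distance in [0, 1]. This matches the
  convention of the R ecology stack rather than SciPy's unnormalized sum
  (exposed via `normalize=False` for cross-checking). A pair of all-zero
  samples gets distance 0 with a warning.
* **Jaccard** (turnover): `1 − |A∩B|/|A∪B|` on presence sets, delegated to
  SciPy's boolean implementation, which computes exactly this.
* **Presence** means intensity strictly above a threshold, default 0 (any
  positive intensity counts — appropriate for background-subtracted
  tables); the threshold is a first-class parameter because a minimum-
  intensity filter is a defensible alternative. **Richness** is the row
  sum of the binarized matrix.

## perMANOVA with restricted permutations

With `d²ᵢⱼ` the squared dissimilarities, `SS_T = (1/N) Σ_{i<j} d²ᵢⱼ`,
`SS_W = Σ_g (1/n_g) Σ_{i<j∈g} d²ᵢⱼ`, `SS_A = SS_T − SS_W`,
`F = (SS_A/(a−1))/(SS_W/(N−a))`, `r² = SS_A/SS_T`. The test is one-way on
the composite condition factor (the factorial cell); sequential
multi-factor decomposition is out of scope.

Significance comes from permuting group labels **within strata** (blocks
or sites), leaving each stratum's label multiset invariant — this is what
makes the test valid under block-level random effects, and the generator
plants such effects precisely so the restriction has something to absorb.
Two modes:

* **exact** (automatic at n ≤ 9): every distinct within-stratum label
  arrangement is enumerated; `p = #{F* ≥ F_obs}/n_arrangements`, observed
  arrangement included, ties counted. On the hand-checkable 1-D instance
  x = (0, 1, 10, 11), groups (A,A,B,B), this gives F = 200 (identical to
  classical one-way ANOVA) and p = 2/6: the complement assignment induces
  the same partition and therefore ties the observed F.
* **Monte-Carlo**: default n_perm = 9,999 (large enough to resolve
  p-values of a few 10⁻⁴), `p = (#{F* ≥ F}+1)/(n_perm+1)` so p is never 0.
  The permutation stream is a seeded PCG64; results are bit-reproducible
  given (seed, n_perm).

`SS_W = 0` (all within-group distances zero) reports F = +∞ with a
degeneracy flag rather than an error.

## Dispersion and mean dissimilarity

PERMDISP embeds the distance matrix by principal coordinates
(eigendecomposition of the Gower-centered matrix), keeping
negative-eigenvalue axes: distance to center is
`z = sqrt(max(0, d²_real − d²_imag))`, the standard correction for
semimetric dissimilarities like Canberra and Jaccard. Group centers are
**spatial medians** by default (Weiszfeld iteration, run separately in the
real and imaginary subspaces), with centroids as an option; the choice is
recorded in the result. A one-way ANOVA F on z is tested by permuting z's
labels. Sums of squares at rounding level (≤ 10⁻²⁰ of the scale of z) are
treated as zero so exactly-equal dispersions reconstructed through the
eigendecomposition report F = 0.

Mean dissimilarity matrices (diagonal = mean within-group, off-diagonal =
mean between-group distance) carry a per-pair flag — between-mean
exceeding both within-means — indicating centroid separation rather than
dispersion as the driver of a significant perMANOVA. Singleton groups have
undefined diagonals, flagged not imputed.

## NMDS

Kruskal stress-1, `sqrt(Σ(d̂ − d)²/Σd²)`, with d̂ the isotonic regression
of configuration distances on the rank order of the input dissimilarities
(primary treatment of ties: tied input values are kept in stable order and
the monotone fit is free within a tie block). Optimization alternates the
isotonic fit (SciPy's PAVA, which is already least-squares optimal in the
configuration's scale — no extra disparity rescaling) with a Guttman
majorization update. Restart 0 starts from classical principal
coordinates, the rest from Gaussian noise; defaults n_restarts = 20,
max_iter = 300, tol = 1e-7 (stress change). The best restart's solution is
returned centered, rotated to principal axes, with a deterministic sign
convention. No "half-change" scaling and no species-score projection: the
ordination is used solely to display sample profiles.

Group uncertainty is a **standard-error ellipse**:
`(x − c)ᵀ(Cov/n_g)⁻¹(x − c) ≤ χ²_k(0.95)` with c the group score mean and
Cov the group score covariance. The χ² quantile (rather than a t/F
small-sample variant) keeps the construction deterministic and simple;
ellipse area therefore scales exactly as 1/n_g. Groups of fewer than 3
samples are skipped with a warning; singular covariances yield a flagged
degenerate ellipse.

## Abundance shifts and bootstrap

Relative change per feature is `100·(mean_cond − mean_ref)/mean_ref` with
arithmetic means over samples, zeros included — means (not medians) are
used throughout, and intensities are raw by default (an optional
per-sample total-intensity normalization exists but defaults off, recorded
in output). Features with reference mean 0 have no defined percent change
and are reported separately. Classification at the default ±75% threshold
is inclusive. Up/down sets are intersected over non-reference conditions
into exclusive Venn regions; counts sum to the union size by construction
(property-tested against brute-force set algebra).

Per-compound CIs are **percentile bootstrap** (default n_boot = 2,000,
95%): resample with replacement independently within condition and
reference, recompute the relative change, take quantiles. Replicates whose
resampled reference mean is 0 are dropped and counted. A condition group
that is entirely zero is the "compound completely absent" case: flag set,
change −100%, degenerate CI. The percentile method was chosen over BCa for
transparency; its known cost is small-sample undercoverage — the
validation study measures ≈90% realized coverage at n = 8 + 8 against a
nominal 95% (the bootstrap variance is biased low at such n, and the
implementation agrees with SciPy's percentile bootstrap on identical
data). Users needing accurate small-sample coverage should increase group
sizes rather than trust the nominal level at n ≤ 8.

## Mixed models

Richness (or a single compound's abundance) is modeled as
`y = intercept + condition + (1|block)` fitted by REML (statsmodels
MixedLM; this package owns the contract — random intercept only,
reference-level contrasts — not the optimizer). Contrasts vs the reference
level get Wald t p-values on a residual-df approximation
`df = n − p_fixed − n_blocks + 1` (recorded in the result); no
Kenward–Roger-type correction is attempted. Zero random-intercept variance
is a valid boundary fit, flagged; a constant response returns a degenerate
all-zero result rather than an optimizer error. In the validation study
the ±2·SE interval captures a true richness shift at a ≈94% rate,
consistent with the t-approximation (P(|t₁₇)| ≤ 2) ≈ 0.94) — the SEs
themselves are well calibrated.

## Synthetic-data generator

The generator emulates exactly the structure the analyses assume:

* a blocked factorial or small observational design (templates: a
  2×3×2 × 6-replicate layout → 72 plots in 3 blocks; a 2×2 × 3-replicate
  layout → 12 plots);
* latent metabolites with uniform RT and masses spaced ≥ 0.05 Da (spacing
  guarantees unambiguous cross-polarity matching when jitter < tolerance —
  deliberate, so fusion recovery can be tested exactly);
* a `shared_fraction` (default 0.3) detectable in both modes, negative
  mass = positive mass − 2.014552 Da, mass jitter ±0.001 Da and RT jitter
  ±0.02 min (both below the matching tolerances);
* intensities `exp(N(μ=13, σ=1.5))` per metabolite — log-normal baselines,
  the standard model for LC-MS intensities — times a per-(block,
  metabolite) effect `exp(N(0, 0.2))`, times mean-one multiplicative noise
  with CV 0.25, times δ for (condition, feature) effect pairs;
* turnover toggles: "loss" features forced absent in a condition, "gain"
  features present only there; plus baseline dropout (a present feature
  reads 0) at rate 0.05;
* per-polarity response factors `exp(N(0, 0.5))` so the two modes of a
  shared metabolite have correlated but unequal intensities (making the
  mean-intensity winner rule non-trivial).

Default scale ~1,900 metabolites and groups of 8–13 samples, the scale of
a single-species season in the motivating field design; smoke-test
configurations go down to 50 features / 3 per group. Identical seeds give
byte-identical output files.

**What passing tests do not show**: the generator draws features
independently (no correlated metabolite families or shared pathways), has
no RT drift, batch effects, isotopes or adducts beyond the one two-proton
relationship, no heteroscedastic detector saturation, and dropout is
independent of intensity (real missingness is abundance-dependent).
Operating characteristics measured on it (type-I error ≈ 0.05 under
strata permutation, power, CI coverage) are statements about the methods
under this clean model, not guarantees on real instrument data.

## Pipeline and determinism

The `run` orchestrator executes simulate/load → trim → fuse → Canberra
(perMANOVA, PERMDISP, mean dissimilarity) → Jaccard (perMANOVA, PERMDISP)
→ NMDS + ellipses → richness LME → shift report, writing a
schema-versioned JSON report that echoes every seed and parameter and
counts features in/out of every filter. Reports contain no timestamps and
are serialized with sorted keys: identical config + seeds ⇒ byte-identical
bytes. Analyses of different years/species are independent runs by
design; the pipeline never pools across years. Stage failures abort with
the stage name; partial outputs are retained.

Validation problem sizes (500 null simulations at n_perm = 999 for type-I
error, 100 for power, 500 outer bootstrap replicates, 300 mixed-model
fits) were chosen to put Monte-Carlo error well below the effect sizes
being checked while keeping the full validation run around a minute.

## Known limitations

* One-way condition factor only; no sequential (multi-factor) distance
  decomposition, no post-hoc pairwise perMANOVA.
* The percentile bootstrap undercovers at very small n (above).
* NMDS stress has no absolute quality benchmark here; acceptance is
  property-based (exact recovery of truly planar geometries, monotone
  stress within restarts, invariances).
* Venn output is counts + memberships; rendering a scaled diagram is left
  to plotting tools.
* No compound identification, adduct networks, or raw-spectra handling —
  the pipeline starts at peak tables.
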