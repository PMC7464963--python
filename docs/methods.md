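# Methods

`cecalomics` implements the statistical chain of a longitudinal broiler
feeding trial in which caecal content was profiled by 1D ¹H-NMR and the
caeca/ileum/litter communities by 16S amplicon tables: three diet groups
(A control, B and C with increasing riboflavin supplementation), sampled at
days 15, 28 and 42 of the productive cycle, 40 birds per room per sampling.
Every stage is driven either by user-supplied tables/spectra or by the
package's own synthetic-data generator, so the full chain is testable
without any external data.

## Synthetic-data generator

**NMR spectra.** A metabolite's latent square-root concentration for a bird
in group *g* sampled at day *t* is

    sqrt(c) = α_g + β_g ln t + ε,   ε ~ N(0, σ_m),

and the concentration is its square, clipped at zero (clips are counted and
warned about). Placing the truth on the sqrt scale means the downstream
square-root transform *exactly* linearizes the generator model, so
parameter recovery is a genuine test of the kinetics stage rather than an
approximation exercise. Spectra are sums of unit-area Lorentzian multiplets
(default linewidth 0.002 ppm — NMR lines are Lorentzian, not Gaussian)
scaled by concentration, plus a TSP reference singlet at 0.00 ppm, a
per-sample calibration offset of the ppm axis (sd 0.003 ppm), and additive
Gaussian baseline noise (sd 0.01 intensity units). The default axis spans
−0.5 to 9.5 ppm at 1.83·10⁻⁴ ppm per point, so 100-point bins are
0.0183 ppm wide. The default trial layout yields 120/119/118 caecal spectra
at the three days (357 total), with the missing samples removed at random
under the design seed.

The default ten-metabolite panel (acetate, butyrate, lactate, propionate,
succinate, formate, pyruvate, aspartate, glutamate, nicotinate) uses
textbook chemical shifts; shifts are configuration, never test assertions.
Each spec's first peak is an isolated "quantification" resonance from which
ppm assignment intervals are derived. Planted group effects are
parameterized so the affected group's curve crosses the shared curve at
day 15 and separates progressively (Δβ = 0.45 on the sqrt scale at noise
σ = 0.35): group B's acetate dampening, group C's butyrate rise and faster
lactate decline become band-resolvable around the second sampling.

**Abundance tables.** Presence of a specified taxon in a sample is a
Bernoulli draw at its stratum prevalence; present taxa get a log-normal
abundance around their ecosystem mean, floored at 0.25% (safely above the
0.1% detection level), absent taxa are exactly 0. The remaining mass in
each sample is shared among unnamed background taxa via a Dirichlet draw
(concentration 0.3, giving the uneven, sparsely-detected background of real
amplicon surveys), so columns sum to exactly 1 and presence/absence of the
specified taxa maps one-to-one onto detection. The presence stream per
ecosystem is a documented, separately-seeded generator so tests can replay
it draw for draw.

**What the generator does not emulate.** No free-induction decays, phase or
baseline errors (the pipeline starts from processed spectra); no
chemical-shift drift dependent on pH or ionic strength; no peak-shape
distortions, no ¹³C satellites; no read-level 16S error, chimeras or
compositional count noise (tables are generated directly on the
relative-abundance scale); no phylogenetic structure. Passing tests
therefore certify the statistical machinery under the stated model, not
robustness to instrument artifacts.

## Spectral pre-processing

Fixed order: calibrate → excise → normalize → bin.

- **Calibration** shifts the axis so the tallest point in the reference
  window (default ±0.2 ppm) sits at 0.00 ppm; it errors when the window
  maximum is within 5 robust SDs of the spectrum median.
- **Excision** defaults: peripheries below 0.5 and above 9.0 ppm and the
  residual water band 4.70–4.90 ppm. All intervals are configuration — the
  appropriate cuts depend on the acquisition.
- **Regional PQN.** The probabilistic quotient normalization uses the
  point-wise *median* spectrum as reference and the *median* quotient as
  the per-sample scale, computed separately for the regions below and above
  a split point (default 4.8 ppm, i.e. the excised water gap). Quotients
  use only points where the reference exceeds machine epsilon. Two caveats
  are worth knowing. (1) PQN is exactly idempotent only for cohorts that
  are scalar dilutions of one shape — for heterogeneous cohorts a second
  pass produces factors near, but not exactly, 1. (2) PQN assumes most of
  the spectrum is invariant across samples; when a large fraction of the
  total signal carries a real time trend, part of that trend is absorbed
  into the scale factors and redistributed across metabolites. This
  compresses fitted slopes (visible in the demo runs) without disturbing
  between-group contrasts at a fixed day, which is what the significance
  calls use.
- **Binning** sums consecutive runs of 100 points (an integral-like
  aggregation — the paper-scale profile has 0.0183-ppm buckets); a trailing
  remainder shorter than one bin is dropped and logged, keeping the bin
  width constant. Binning is mass-conserving over the retained points and
  invariant under whole-axis translation.

## PLS-DA, weight smoothing, peak selection, classification

The discriminant analysis is a PLS2 regression of the column-centered bin
matrix on the centered one-hot class matrix, computed with the NIPALS
iteration (tolerance 10⁻¹⁰ on the weight update, 500 iterations per
component, error on non-convergence) and X-deflation; weight vectors are
unit-norm and score vectors mutually orthogonal. The first weight vector
equals the dominant left singular direction of XᵀY, which the tests verify
against an independent SVD. Class prediction uses the indicator regression
with ties broken in sorted class order.

Candidate discriminant bins are read from a component's weight vector after
(1) Savitzky–Golay smoothing (window 11, polyorder 3 — exact on cubic
segments) and (2) subtraction of an asymmetric-least-squares baseline
(second-difference penalty λ = 10⁵, asymmetry p = 0.001, 10 solves; one
solve with symmetric weights is the Whittaker smoother). Peaks are local
maxima of the absolute smoothed weights whose signal-to-noise ratio exceeds
a threshold (default 3). The noise scale is the *centered standard
deviation* of the smoothed vector inside a designated peak-free window; a
scale based on the standard deviation of absolute values would
systematically understate Gaussian noise by ~40% and let pure-noise maxima
through any threshold near 3.

Group discrimination is scored by stratified 10-fold cross-validation of a
linear soft-margin SVC at C = 0.01 (the fixed optimum; a seeded random
search helper exists but the default pipeline does not re-search). Features
are standardized inside each training fold: the arbitrary A.U. intensity
scale makes raw PLS scores O(10⁴), where a fixed C is meaningless and
libsvm converges pathologically slowly. Scaling is fold-local, so there is
no leakage.

## Kinetics

Per metabolite and group, sample signals (sums of assigned bin values, in
A.U.) are square-root transformed; the per-day means Y are fit with a
Gaussian-family identity-link GLM, Y = α + β ln t (natural log — the slope
scale depends on this choice, so it is stated everywhere). The GLM is fit
on the per-day means, unweighted by default (cell sizes are nearly equal by
design; weighting is exposed as an option), with the bootstrap carrying the
sample-level variability: each of n_boot = 2000 replicates resamples every
(group, day) cell with replacement, recomputes sqrt-means and refits.
Because the Gaussian identity-link GLM on the means coincides with ordinary
least squares, the bootstrap refits use the closed-form normal equations,
vectorized over replicates.

The 95% band is a percentile interval with Hesterberg's small-sample
expansion of the quantile levels (computed from the smallest cell size).
Calibration runs at n = 40/cell showed the plain percentile band covering
the true curve only ~93% of the time at the leverage-heavy first sampling
day; the expanded levels restore ~95% at all three days while remaining a
percentile-type interval. Zero-variance cells collapse the band to zero
width; a constant response (where the GLM deviance guess degenerates) falls
back to the mathematically identical weighted least squares.

Two groups are called significantly different (p < 0.05 in the
interval-overlap sense) on days where their bands are disjoint. The
significance report flags a pair when the trailing run of disjoint days —
the run reaching the end of the 100-point day grid — spans at least 4 days;
the minimum span guards against borderline band contact at the grid edge.
The first day of that run is reported as the separation onset.

## Microbiota statistics

- **Detection** means relative abundance strictly above 0.1%; **core**
  membership requires detection in strictly more than 90% of a time point's
  samples for at least one time point. Both inequalities are strict exactly
  as the rules are printed, and boundary tests pin this.
- **Filtering** for compositional analysis keeps taxa at ≥ 0.5% abundance
  in ≥ 1% of an ecosystem's samples (inclusive); values are not
  renormalized. Filtering and the core rule are independent and both
  operate on the unfiltered table.
- **Differential abundance**: Kruskal–Wallis across groups per taxon per
  time point (mid-rank ties), Benjamini–Hochberg correction within each
  (ecosystem, time point) family — whether the original analysis pooled
  across time points is not stated, so the per-time-point family is the
  documented choice; significance at q < 0.05. All-tied taxa get p = 1 with
  a warning.
- **Alpha diversity**: observed richness above a detection threshold and
  Shannon entropy in log base 2 (consistent with customary amplicon-survey
  magnitudes; the base is configurable).
- **Prevalence matrix**: percentage of each (ecosystem, group, time)
  stratum's samples carrying each core taxon above detection.
- **Ecological grouping**: the published figure's G1–G9 assignment has no
  stated algorithm (it appears manual), so the default is average-linkage
  hierarchical clustering of prevalence profiles (Euclidean), cut to k
  groups labelled in dendrogram leaf order for determinism; a rule-based
  mode grouping taxa by their ecosystem-persistence pattern is provided for
  reproduction of figure-style layouts.

## Orchestration and reproducibility

A single global seed fans out to stage seeds through a fixed
`SeedSequence` derivation, so stages are independently reproducible; every
report carries the SHA-256 hash of its canonicalized configuration, and
re-running an identical configuration is byte-identical. The command-line
interface (`simulate`, `preprocess`, `chemometrics`, `kinetics`,
`microbiota`, `run-all`) is a thin layer over the library functions, with
spectra as two-column CSV, matrices and tables as TSV, and configuration
and assignments as YAML.

## Problem sizes used in the test suite

Unit tests run a reduced trial (5–20 birds per cell on a 4× coarser ppm
axis with 25-point bins, preserving the 0.0183-ppm bin width); the
acceptance-style checks run the full 357-spectrum trial, 200 recovery
replicates, 2000 coverage replicates with 1000 bootstrap resamples each,
and 100-seed power/null simulations for the differential-abundance stage.

## Known limitations

- Regional PQN redistributes strong shared trends (see above); slope
  *magnitudes* after normalization are not comparable to generator truth,
  only contrasts between groups are.
- Band non-overlap is a conservative significance criterion; two groups
  can differ at p < 0.05 while their 95% intervals still overlap.
- The kinetics model is a two-parameter log-linear trend on three time
  points — it describes monotone saturating kinetics, not mechanistic
  (ODE) dynamics, and cannot represent non-monotone time courses.
- Absolute quantification is out of scope: all signals are normalized
  arbitrary units, proportional to concentration.
- The ecology grouping is a descriptive clustering; different k or metrics
  give different partitions, and labels are not comparable across runs with
  different core sets.
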