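# Methods

## Scope and model of the data

`estuarynet` re-implements, as one tested pipeline, the statistical workflow
used to analyse sediment microbiomes along a polluted land–sea transect:
community dissimilarity statistics and their permutation tests,
environment–taxon association screens, functional-category comparisons, and a
co-occurrence network whose correlation threshold is chosen by random-matrix
theory (RMT), followed by module eigengenes, Zi/Pi node roles and keystone
identification. The sampling design it targets is small-n by nature — a
handful of sites sampled in two years (12 samples) — which shapes most of the
numerical choices below.

## Synthetic transect generator

Because the original sequence data are external, every stage is validated on
a generator with known ground truth. It emulates:

- **Environment.** Each factor follows a linear gradient over transect
  position plus Gaussian noise (`Gradient(start, end, noise_sd)`), with
  endpoints set to field-realistic values: salinity 3→23 ‰, depth 6→30 m,
  pH 7.7→8.3 rising seaward; COD, seawater ammonia (0.8→0.05 mg/L), DIN
  (3.5→0.4 mg/L) and TP (0.20→0.03 mg/L) falling seaward, mimicking
  land-sourced pollution. The three seawater pollutants share an
  equicorrelated noise block (default pairwise ρ = 0.9), reproducing their
  common source. Coordinates sit on an evenly spaced line; samples carry
  inner/outer group labels (3 + 3 sites × 2 years).
- **Community.** 300 OTUs; per-OTU log-abundance = baseline (SD 1 across
  OTUs) + guild effect × standardized driver + correlated noise. A guild is a
  block of OTUs with a common driver response (`effect_size` in log units per
  driver SD) and within-guild noise correlation ρ (default 0.8), implemented
  with a shared per-sample latent factor. Counts are multinomial draws on the
  softmax of log-abundances at fixed depth (default 10⁵), accepting the
  compositional coupling that fixed-depth sequencing imposes.
- **Guild design.** The default plants four 40-OTU guilds: one driven by
  seawater DIN (effect 2) and three environment-neutral. Only one guild is
  gradient-driven *by design*: on a one-dimensional transect every monotone
  factor is collinear with every other, so two strongly driven guilds would
  have inter-block correlations near |r| ≈ 0.7 and the planted module
  partition would not be identifiable by any method — an ill-posed ground
  truth, not a harder test. The remaining 140 OTUs are uncorrelated
  background.
- **Function.** Level-4 gene functions in a 4-level hierarchy; level-1
  category shares follow the observed shape of sediment metagenomes: five
  house-keeping categories (carbohydrates, amino acids, protein metabolism,
  cofactors, RNA metabolism) carrying ≈44 % of sequences, with the
  ecologically informative categories (N, S, P metabolism, stress response,
  aromatic compounds, plasmids/transposable elements) at the 1–2 % scale.
  Counts are Dirichlet-multinomial; the concentration (2×10⁴) puts the
  between-sample CV of a 2 % category near 5 %, matching the well-known
  stability of level-1 functional profiles. Planted shifts multiply a
  category's expected share by 1.5 in one sample group (N and S metabolism up
  in the outer bay, aromatic-compound metabolism up in the inner bay).

What the generator does **not** emulate: phylogenetic signal in guild
membership (the random tree is independent of guilds), temporal
autocorrelation between years, overdispersion beyond the multinomial for
OTU counts, and spatial structure beyond a single axis. Passing tests
therefore demonstrate correctness of the statistical machinery under a
realistic effect/noise geometry, not robustness to every property of real
amplicon data.

All randomness flows from one integer seed through `numpy.random.Generator`;
no global RNG state is touched.

## Dissimilarities

Bray-Curtis works on row-normalized relative abundances by default (library
size is an artifact); Sørensen is Bray-Curtis on presence/absence.
Environmental Euclidean z-scores each factor first (units are
incommensurate) and excludes coordinate-role columns; the unstandardized
variant is a flag, and the choice is recorded in the metric name. UniFrac
(both variants) delegates to scikit-bio; weighted UniFrac is the normalized
variant so entries stay in [0, 1]. Geographic distance is the haversine
great-circle length with Earth radius 6371 km.

## Permutation tests

MRPP (δ = Σ (nᵢ/N)·mean within-group distance, chance-corrected
A = 1 − δ/E[δ] with the exact E[δ] = overall mean pairwise distance), ANOSIM
(Clarke's R on average-ranked distances, denominator n(n−1)/4 so perfect
separation gives R = 1), one-factor PERMANOVA (Anderson's pseudo-F from the
distance matrix directly), and simple/partial Mantel (Pearson by default on
the condensed vectors, Spearman by flag; the partial statistic is the
first-order partial correlation, permuting the first matrix). All use the
(1 + b)/(1 + n_perm) estimator — p is never exactly 0 — with n_perm = 999 by
default, and switch to exhaustive enumeration of all n! sample permutations
whenever n! ≤ n_perm, which makes the n ≤ 6 toys exact. One deliberate
degenerate case: when the control matrix equals an input (partial r is 0/0),
the full-control limit 0 is returned rather than an error.

## Association screens

Features are transformed to log10(relative abundance + 10⁻⁶) before Pearson
(heavy-tailed abundances; the raw option is kept and recorded in output
metadata). The feature × factor screen is BH-adjusted as a single family;
zero-variance features yield flagged NaN records excluded from the family.
Partial correlations use the first-order closed form with a t-test on n − 3
degrees of freedom; controls collinear with an input (1 − r² < 10⁻¹²) are
errors. Significance marks follow the usual convention
(· 0.1, * 0.05, ** 0.01, *** 0.001).

## RMT threshold selection

The co-occurrence network's similarity is |Pearson r| between transformed
OTU profiles (signs kept as edge attributes). The threshold scan zeroes
entries below each candidate t (grid 0.30–0.99, step 0.01), drops rows with
no surviving off-diagonal entry, and tests the nearest-neighbour spacing
distribution (NNSD) of the unfolded spectrum against the Poisson law e^(−s)
(modular, system-specific structure) and the Wigner surmise
(π s/2)·e^(−π s²/4) (GOE, noise). The chosen cutoff is the smallest t that
is Poisson-consistent (χ² p > 0.05) at two consecutive grid points (a
persistence rule against single-point flicker).

Numerical choices, calibrated on reference ensembles (iid spectra and
dim-500 GOE matrices) before any downstream test was written:

- **Unfolding**: monotone PCHIP interpolation through a decimated empirical
  spectral CDF with ~n/15 knots. More knots (n/10) track sampling clumps and
  systematically reject the Poisson law on genuinely Poisson spectra.
- **Edge trim**: 5 % of eigenvalues discarded at each spectral edge, where
  any unfolding is least reliable (classical practice for GOE edges).
- **χ² binning**: width 0.1 on s ∈ [0, 3] plus an open tail bin, pooling
  adjacent bins until each expected count is ≥ 5 (the textbook rule; pooling
  at ≥ 1 leaves sparse tail bins that inflate the type-I error),
  dof = bins − 1.

With these settings the Wigner law is accepted on ~96 % of GOE replicates
and the Poisson law on ~97 % of iid replicates, with cross-rejection ≈ 100 %.
A pure-noise correlation matrix — the GOE archetype — never shows a Poisson
transition before the thresholded matrix collapses below the 50-eigenvalue
floor; the scan then raises an error carrying the full scan table. This is
the scientifically correct behaviour: the Poisson onset marks emerging
modular structure, and noise has none.

## Network analysis

Edges connect pairs with |r| ≥ cutoff; isolated nodes are dropped. Modules
come from fast-greedy (Clauset–Newman–Moore) modularity maximization on the
unweighted graph (networkx), reported with Q. Null comparison uses
Maslov–Sneppen degree-preserving rewiring (10×|E| accepted double-edge
swaps, 100 replicates by default) with z-scores for every index, including
Q re-optimized on each rewired graph. Topological indices: average degree,
triangle-based average clustering (degree-<2 nodes contribute 0), average
shortest path on the largest component, and the R² of a log-log linear fit
to the degree distribution as the scale-free proxy.

Module eigengenes are the first sample-side singular vector of the module's
feature-standardized abundance submatrix, computed for modules with more
than 5 members, sign-fixed so the mean correlation with member profiles is
non-negative, and reported with σ₁²/Σσ² variance explained. Node roles use
the Guimerà–Amaral plane: within-module degree z-score Zi (0 when the
module's spread is 0) and participation coefficient Pi = 1 − Σ (k_is/k_i)²,
with the conventional thresholds Zi > 2.5 (module hub) and Pi > 0.62
(connector); both thresholds are arguments, since this convention is a
community default rather than a derived quantity. Keystones are the union of
non-peripheral nodes and the top-10 degrees (ties at rank 10 included),
deterministically ordered.

## Functional profiles

Depth normalization rescales each sample to a common real-valued total
(default 20,634,952 — the annotation pipeline convention this workflow
follows); no resampling, so proportions are exactly preserved and
normalization commutes with hierarchy aggregation. Category-level group
comparison defaults to a two-sided Welch t on relative abundances with BH
adjustment (Mann–Whitney by flag; degenerate-variance categories fall back
to the rank test) — the underlying study does not name its test, so the
choice is explicit in the output metadata.

## Problem sizes and validation

The validation suite (`estuarynet.benchmarks`, run by the acceptance tests
and `scripts/acceptance.py`) uses: 1000 null-transect replicates with
n_perm = 99 for type-I calibration (the binomial 95 % CI at α = 0.05 is then
[0.036, 0.064]); 100 replicates per reference ensemble at dimension 500 for
the NNSD laws; 20 scenario seeds for planted-module recovery (scored by
adjusted Rand index over guild-member nodes, and by the |r| between the
pollutant module's eigengene and the planted driver); and exact closed-form
graph identities (two disconnected 5-cliques: Q = 0.5; K₅ clustering 1;
P₄ mean path 10/6; balanced bridge node Pi = 0.5). Typical results: null
rejection 0.045–0.055 for all four tests, median ARI ≈ 0.98, median
eigengene–driver |r| ≈ 0.91, and a median RMT cutoff of 0.75–0.80 at
12 samples — consistent with the ~0.8 cutoffs reported for real 12-sample
estuarine OTU tables.

## Known limitations

- The RMT scan needs ≥ 50 non-isolated features at a candidate threshold;
  very sparse or tiny tables cannot be scanned.
- The one-factor PERMANOVA covers the design used here (a single grouping);
  multi-factor or stratified designs are out of scope.
- Compositional artifacts of relative-abundance correlation (spurious
  negative correlation at fixed depth) are not corrected; SparCC-style
  estimators are out of scope, and correlations should be read accordingly.
- Partial Mantel controls exactly one matrix; higher-order partials are not
  implemented.
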