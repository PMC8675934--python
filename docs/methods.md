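# Methods

This note records the models, parameters and numerical choices behind
`commstack`, and what the synthetic-data experiments do and do not show.

## The prediction problem and the stacked resolution

The observational unit is a *community*: one 1 m² subplot in one year,
with integer counts of adult individuals for each of `m` species, a
13-variable soil profile measured once per subplot (pH, total salinity,
carbonates, organic matter, C/N ratio, Cl, C, N, P, Ca, Mg, K, Na), and
the year's precipitation. All modelling runs on a single stacked design
matrix: one row per (focal species, community), with the retained
abiotic features, optionally one competitor-abundance column per
species, and a one-hot species-identity factor. One global model serves
every focal species. Two rules are enforced structurally:

- **zero-out**: the competitor column matching the row's focal species
  is always 0 — the focal's abundance is the target and must never leak
  into its own features;
- **no clipping**: linear and boosted models may predict negative or
  fractional abundances and these are preserved, so that model families
  are compared on the scale they actually predict.

The two-step ensemble fits an abiotic-only stage 1, computes its
predictions for every (species, community), binds them as competitor
columns (zero-out applied), and fits stage 2 on that semi-synthetic
frame. Chaining is *in-sample* by default (stage 1 predicts its own
training data); *out-of-fold* chaining (K-fold held-out stage-1
predictions, default 5 folds) is available as an anti-leakage variant.
Stage seeds are derived from one user seed through `SeedSequence`, so
the stages are independently reproducible. At prediction time the
interface accepts abiotic records only and raises if any observed
abundance column is present.

## Model families and defaults

`ModelSpec` wraps three families: ordinary least squares, random forest
(default 500 trees, unlimited depth, 1/3 of features per split), and
XGBoost (default 500 rounds, depth 6, learning rate 0.1, hist method).
All run single-threaded with a recorded seed; `max_samples` exposes the
forest's per-tree bootstrap fraction. Hyperparameter search is out of
scope.

The *evaluation protocol* used in the test suite and examples is
smaller than the library defaults: 80 trees, bootstrap fraction 0.25,
all features per split, and a depth-6 stage-1 forest for the two-step
model. These sizes were chosen once as a single-CPU protocol (tree count first for variance
reduction, aggressive subsampling for speed); the
depth-limited stage 1 also reduces the gap between its in-sample
(chained) and out-of-sample prediction distributions, which stabilises
the two-step comparison.

## Feature selection

Stage one computes the pairwise Spearman matrix over the abiotic
candidates and groups features into clusters by transitive |ρ| ≥ 0.7
(the threshold separates the survey's two soil clusters,
{C, organic matter, N, C/N} and {salinity, Na, Cl, K}, and is
configurable). One representative is kept per cluster — a manual
keep-list wins, otherwise the member with the highest marginal |ρ|
against total community abundance. Constant features are flagged and
kept (their rank correlation is undefined). Stage two appends a uniform
random-noise column, fits the requested model on an 80 % split, and
measures each feature's permutation importance (mean drop in held-out
R² over 10 shuffles; the one-hot species columns are shuffled jointly as
a single *species* factor). Features below the noise benchmark can be
dropped automatically, subject to manual keep/drop overrides; the
shipped case-study rules reproduce a 6-feature abiotic set (salinity,
carbonates, C, P, Ca, precipitation — Ca retained by explicit override)
and an 8-feature full set (adding pH and Mg).

A caveat established during development: a feature with exactly zero
causal effect and the injected noise column both have importances
statistically indistinguishable from zero, so their *ordering* is close
to a coin flip. The below-noise rule is therefore a screening heuristic,
not a test; the suite asserts the stable facts (true drivers far above
noise, inert features far below the drivers) rather than the unstable
pairwise ordering.

## Evaluation protocols

RMSE and R² use the standard definitions (R² = 1 − SS_res/SS_tot with
SS_tot about the observed mean; RSE ≡ 1 − R²); R² may be negative and a
zero-variance target is an error. Global scores pool the stacked
predictions across species; per-species scores use the species' own
mean, and species with zero-variance observations are flagged rather
than scored.

Spatial block K-fold groups subplots into axis-aligned 3 m × 3 m blocks
within each plot (four blocks of nine subplots in a 6×6 plot) and deals
whole blocks to k = 4 folds balancing subplot counts; all years of a
subplot share its fold. Repeated random holdout redraws an 80/20
community-level split (default 100 runs). Leave-one-year-out trains on
all other years, *including later ones* — it evaluates temporal
transferability of the procedure, not a forecast — optionally with the
precipitation feature removed. Moran's I uses row-standardised weights
(inverse distance by default, rook adjacency as an option); the
per-species survey statistic averages I over (plot, year) fields,
skipping fields where the species is absent or constant.

## The synthetic community generator

No field data ship with the package, so the generator is the test bed.
It emulates a five-year survey of 23 annual species on a 9-plot salinity
gradient (plots 120 m apart, 6×6 subplots of 1 m²), with soil measured
once per subplot and year-level precipitation spanning 384–625 mm.

Landscape: soil variables are drawn from latent axes — a plot-level
salinity gradient plus i.i.d. subplot noise — with cluster members
loading √r on a shared factor (default rank correlation r = 0.9 inside
the carbon and salinity clusters). pH, Ca and Mg are emitted but have no
effect on any species: they exist to exercise feature selection.

Abundances, per species i and community s:

1. *Niche.* A log-linear response to the standardised **measured** C,
   carbonates and P columns, plus a quadratic (Gaussian) niche on
   standardised salinity, saturated through `cap·tanh(·/cap)`
   (cap = 2.2) so stands plateau at a carrying density; a species'
   log-linear year effect (|slope| 0.4–2.0, random sign) multiplies
   recruitment outside the cap. Interpolation of response scale, niche
   width, year effect, dispersion and patchiness along each species'
   abundance rank makes dominants the more responsive, concentrated and
   weather-sensitive species.
2. *Competition.* Beverton–Holt suppression
   `N = K / (1 + Σ_j α_ij K_j)` with α ≥ 0, a guaranteed self-regulation
   diagonal, interaction strengths scaled by the competitor's dominance
   rank, and α rescaled by mean interaction-free abundance so
   denominators are O(1).
3. *Hurdle and counts.* Establishment succeeds only in a species'
   better-than-typical sites: occupancy is Bernoulli with logit
   `a_i + 3·(log N − median_i log N)`, the intercept declining from +0.6
   (rare) to −5.2 (dominant) with per-species jitter ±0.8. Occupied
   communities draw negative-binomial counts around N (dispersion k
   from 4.0 down to 1.5 with dominance; a mild mean-corrected lognormal
   patchiness term adds within-stand clumping). About a quarter of the
   mid-ranked species are *generalists* — broadly tolerant, evenly
   spread, near-Poisson — and two are clumped specialists; together they
   provide the scatter around the Taylor trend that real surveys show.

Design rationale: every mechanism that concentrates populations is
deterministic given the measured soil (saturating niches, relative-
suitability occupancy) or given species identity (rank interpolations,
jitters) or given the observed year (precipitation boom–bust). This was
a deliberate resolution of a real tension — unpredictable aggregation
(i.i.d. lognormal site noise, random occupancy bursts) can reproduce the
same summary statistics but destroys spatial predictive skill, which
contradicts how predictable real communities of this kind are. Under the
committed defaults the generator yields, over seeds: ~75 % zeros,
Taylor exponent ≈ 2.07 with adjusted R² ≈ 0.97, per-species Moran's I
≈ −0.02, abiotic random-forest spatial-holdout R² ≈ 0.5 with the
two-step and all-features variants within a few hundredths of it,
linear regression far behind, and leave-one-year-out R² near or below
zero.

What passing tests on this generator do **not** show: the generator has
no residual between-species correlation beyond what soil and weather
induce (no shared unobserved micro-habitat), no dispersal limitation,
seed banks or flooding dynamics, and its species-parameter draws are
exchangeable rather than taxonomically structured. One consequence is
measurable: because both the abiotic-only and the two-step model see
only abiotic data at prediction time and nothing latent links species
beyond that data, the two-step model cannot *systematically* beat the
abiotic model here (at zeros or overall) — the suite asserts parity,
not superiority. On real data, where unmodelled shared micro-habitat
structure exists, the stacked representation may add more. More
generally, results transfer to real data only insofar as real
abundances are, like the synthetic ones, largely determined by
measurable site and year properties.

## Mechanistic annual-plant model

The Beverton–Holt map `E[X_i] = λ_i(E)·X_i / (1 + Σ_j α_ij(E)·X_j)` is
implemented with log-linear covariate modulation of fecundity
(λ_i(E) = λ_i·e^{β_i E}) and additive modulation of interactions
(α_ij(E) = max(0, α_ij + γ_ij E); clipping, not soft-plus). Fitting is a
within-season snapshot — focal abundance regressed on co-occurring
competitors and the covariate — because germination and seed-survival
fractions are unobservable in a single census. Each focal species is
fitted independently by trust-region least squares on log1p abundances
with a ridge penalty (default 0.1) on the interaction terms; the
covariate is standardised internally and the centring recorded. Held-out
RMSE (20 % of communities) is reported on the natural scale.

Identifiability caveat: data on a one-dimensional environmental manifold
(e.g. a self-consistent equilibrium driven by a single covariate) cannot
pin down interactions and fecundities jointly; parameter-recovery tests
therefore use exogenous competitor variation, under which recovery is
within ~5–7 % (10 % asserted). The covariate-modulated fit beats the
biotic-only fit out of sample whenever the data-generating process
actually uses the covariate — the package's demonstration of the
data-driven → mechanistic feedback.

## Numerical and degenerate-input choices

- Identical config + seed ⇒ bit-identical tables (one `SeedSequence`
  spawns the landscape, parameter and count streams).
- Taylor's-law fit: OLS of log10 variance on log10 mean across species;
  species with zero mean or variance are excluded; fewer than two
  scoreable species is an error ("degenerate abundance distribution").
- Moran's I: fewer than 3 sites or a constant field is an error;
  expectation under randomness is −1/(n−1).
- Fold assignment: blocks are dealt largest-remaining-capacity-first to
  the currently smallest fold; fewer blocks than folds is an error.
- Mechanistic optimisation: bounds keep α ≥ 0 and log λ in [−10, 20];
  non-convergence raises with the solver's diagnostics.
- CSV I/O is RFC-4180 UTF-8 with '.' decimals; schemas can be given
  explicitly (YAML) or inferred from the header (canonical soil names;
  all other non-key columns are species codes).
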