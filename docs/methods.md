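# Methods

This note documents the models, samplers, parameter choices and
numerical conventions used by `mosaicmove`, and what the synthetic
studies do and do not demonstrate.

## Data model and preprocessing

Telemetry is a set of per-individual, time-ordered GPS fixes at a
nominal fixed interval (default 20 min). A *step* joins two consecutive
fixes; its length `d` (m) is the planar Euclidean distance, its duration
`t` (min) the timestamp difference, and its turning angle `θ ∈ [−π, π]`
the signed heading change from the previous step (positive = left).
Geographic input is projected to the UTM zone of the track centroid with
an in-package transverse-Mercator implementation (WGS84, classic series;
sub-metre accuracy within a zone), because every downstream formula
requires metre-true distances. Local clock time uses a configurable UTC
offset (default −4, standard time of the study region); diel summaries
in UTC would be meaningless.

Cleaning applies, in this order:

1. **speed outliers** — steps with `d` strictly above the individual's
   empirical 99th percentile (type-7, linear interpolation) are flagged.
   The threshold is computed per individual over *all* of that
   individual's steps, flagged rows included, which makes the filter
   idempotent; per-individual (rather than global) thresholds respect
   differences in gait and collar performance.
2. **long gaps** — steps spanning strictly more than 60 min (three or
   more missed fixes) are flagged.
3. **zero flooring** — only on the copy of the table feeding the
   traversal-time model, `d = 0` becomes `d = 1` m (the model uses
   `log d`). Floored steps keep no turning angle.

Filters flag rows instead of dropping them, so removal counts are
exact and the turning-angle chain can be recomputed: `θ` is missing
wherever the immediately preceding step of the same individual was
removed or floored, or either segment has zero length.

## Buffered-path land-cover composition

Each step's segment is buffered by 30 m (Minkowski sum with a disc,
round caps) and the class proportions inside the buffer extracted from
the 30 m categorical raster. Membership is computed per cell as an
approximate *coverage fraction*: `clip(½ + (R − dist)/cell, 0, 1)`,
a linear ramp in the distance from the cell centre to the segment.
A binary cell-centre rule was rejected: with 30 m cells and a 30 m
buffer a typical step's buffer holds only ~10–40 cells, so one boundary
cell swings a proportion by several percent (measured worst-case error
0.06 against a 100k-point Monte-Carlo area oracle); the coverage ramp
reduces the worst case to 0.019 at identical cost — one vectorized
distance evaluation over a bounding window.

The choice set of the selection model adds four alternatives of the
observed length pointing east, west, north and south from the step's
start. Alternatives are never clipped: if less than half of an
alternative's buffer weight lies inside the raster the whole choice set
is marked invalid and excluded from the selection model (the observed
row still feeds the time model).

**Rare-class pruning.** A class is dropped when *every* individual's
mean observed-path proportion of it is below 10%. "Consistently rare"
is read as the per-individual mean (not max or median) — the most
direct reading and the least sensitive to single extreme steps. Dropped
mass is redistributed proportionally over the retained classes; a path
composed entirely of dropped classes (possible only in synthetic
corner cases) is assigned to the baseline. The baseline class (pasture,
the dominant cover) must survive pruning; the canonical class order is
forest, savanna, wetland, eucalyptus, mosaic, pasture.

## Time-explicit habitat selection

Fitted independently per individual (no pooling, no random effects;
separate models also dampen temporal autocorrelation). Compositional
covariates are the retained non-baseline class proportions; pasture is
the implicit remainder, which is why results are reported as ratios
rather than raw coefficients.

**Time submodel.** `log t_i ~ Normal(β₀ + γ·log d_i + Σₖ βₖ p_ik, σ²)`
with priors `Normal(0, 10²)` on β₀, γ, βₖ and `Half-Normal(0, 5)` on σ.
The sampler is Gibbs for the coefficient block (its conditional given σ
is exactly multivariate normal) and an adaptive random-walk Metropolis
step on `log σ` (target acceptance 0.44, adapted during burn-in).
Passing a fixed σ turns the fit fully conjugate — used by the test
suite's closed-form oracle. A covariate with zero variance across an
individual's steps is dropped for that fit with a warning.
**Time ratio** of class *a* vs *b*: per-draw `exp(β_a − β_b)` with
`β_baseline ≡ 0`; a 95% equal-tailed interval entirely above 1 means
significantly slower (more time) in *a*.

**Selection submodel.** Conditional logit over the five candidates:
`P(chosen) = exp(α·p_obs) / Σⱼ exp(α·p_j)`. Step length and duration
are identical across candidates by construction and cancel. Priors
`Normal(0, 10²)`; sampler is an adaptive isotropic random-walk
Metropolis (scale adapted toward acceptance 0.3, inside the 0.2–0.4
band, during burn-in). Complete separation is survivable — the prior
keeps the posterior proper — and is flagged via the MAP norm.
**Odds ratio** `exp(αₖ)`: interval above 1 = selection of a pure-class-k
path over a pure-pasture path, below 1 = avoidance.

Significance everywhere is the 95% equal-tailed credible interval
excluding the null — the standard Bayesian analogue of the reported
"statistical" counts. Population tallies count significant individuals
per class and direction, overall and by sex (post-hoc stratification),
with denominators equal to the individuals for which the class was
retained.

Defaults: 3 chains × 4000 iterations, 2000 burn-in, thin 1. Summaries
report posterior mean/sd/quantiles plus split-R̂ and effective sample
size (via ArviZ); split-R̂ > 1.05 on any parameter emits a warning.

## Behavioural-state HMM

Two states are fixed a priori — resting and active — matching the
biology (long rest bouts vs foraging movement) and keeping states
comparable across individuals. Emissions are categorical over eight
step-length bins (breaks 0, 30, 60, 90, 120, 150, 180, 210, 512 m;
bins half-open `[lo, hi)`, lengths above 512 m clamped into bin 8 —
rare after the top-1% filter since 512 m sits at the 99.9th percentile)
and eight equal turning-angle bins on [−π, π] (+π included in bin 8).
Step and angle bins are treated as conditionally independent given the
state (2×8 + 2×8 parameters) rather than one 2×64 joint categorical —
a parsimony choice that keeps the emission tables identifiable at
per-individual sample sizes. Missing angles (burst starts, zero-length
or floored steps) contribute a factor of 1, not an imputation.

Steps are grouped into *bursts* — maximal runs of contiguous retained
steps (optionally also broken where the duration departs from the
nominal interval); the chain is independent across bursts.

The Gibbs sampler alternates (a) exact forward-filter backward-sample
draws of the latent states per burst and (b) conjugate Dirichlet(1,…,1)
updates of the initial distribution, transition-matrix rows and
emission rows from state counts. Default 1000 iterations with 500
burn-in. The per-iteration log-likelihood (from the forward-pass
normalizers) is stored for trace inspection plus a Geweke z-score
(batch-means standard errors, first 10% vs last 50%).

**Label switching** is resolved deterministically at every stored
iteration: "resting" is the state with the smaller expected step-bin
index `Σ_b b·λ_step[state, b]`; an exact tie keeps state 1 as resting.
**Decoding** exports both estimators: the average of per-iteration
sampled states (marginal over parameter uncertainty) and the smoothed
forward–backward `P(active)` at the labeled posterior means; modal
labels threshold at 0.5. Emission probabilities are floored at 1e-300
to keep zero-probability observations finite.

## Diel activity report

Each retained step gets the dominant class of its observed-path
composition (ties broken by canonical class order), a two-hour local
diel bin (twelve bins `[00–02) … [22–24)` partitioning the 24-hour
day), and its modal HMM state. The diel table pools steps (every step
weighs equally; per-individual tables are also emitted for the
alternative weighting), reports `n` for every cell of the full
class × bin grid, flags cells with n < 20 as low-support, and includes
a probability-weighted resting proportion alongside the modal one.

## Synthetic data: what it emulates and what it does not

Landscapes are smoothed Gaussian random fields sliced at the
cumulative-proportion quantiles of the requested class mix (default:
50% pasture, 20% forest, 15% savanna, 5% each wetland / eucalyptus /
mosaic — a pasture-dominated mosaic), with `patch_scale` setting patch
size. Quantile slicing makes realized shares essentially exact.

Trajectories follow the fitted models' assumptions by construction:
a latent resting/active Markov chain (diagonal 0.9) draws step-length
bins (resting mass on bins 1–2, active on 4–8) uniform within bins;
headings are chosen among K = 8 evenly spaced candidates (deliberately
finer than the fitted model's four cardinal alternatives, so the
model's discretization is not baked into the truth) with probability
∝ `exp(α·p)` of the candidate's buffered composition, α = 0 while
resting (defaults: forest 1.0, savanna 0.8, wetland 0.6, eucalyptus
0.3, mosaic 0.1). A ground-truth traversal time
`log t = β₀ + γ·log d + Σ βₖ pₖ + N(0, σ)` (defaults β₀ = 1, γ = 0.2,
σ = 0.3; β: forest 0.5, savanna 0.4, wetland 0.4, eucalyptus 0.2,
mosaic 0.1 — slower in native classes) is stored alongside the nominal
timestamps. An optional `rest_bias` concentrates resting in chosen
classes and hours (used for the diel sign checks). Defect injection
deletes interior fixes (gaps), displaces fixes 2–5 km (outliers, kept
below ~1% of steps so they sit strictly inside the top-1% tail) and
duplicates coordinates (zero steps), recording exact labels. All
randomness flows from one seed through named sub-streams
(`SeedSequence(seed, spawn_key=(purpose, individual))`), so oracles can
re-draw any decision independently.

Direct model-level simulators (`simulate_choice_sets`,
`simulate_time_steps`) draw from the likelihoods themselves for
coverage and recovery studies; choice-set compositions use
Dirichlet(0.3), clustering near single classes as 30 m buffers in a
patchy mosaic do.

*Limits.* The simulator makes no attempt to reproduce real home-range
geometry, seasonal (wet/dry) structure, temperature-driven behaviour,
or spatial/temporal autocorrelation beyond the state chain; passing
recovery tests demonstrates the estimators are correct under the
models' own assumptions, not that the models are adequate for any
particular field dataset. With nominal fixed-interval timestamps the
time submodel's regressors carry no signal in fully synthetic
pipeline runs; time-model recovery therefore uses the stored
ground-truth traversal times.

## Problem sizes and numerical conventions

Recovery and coverage studies use 2000–5000 steps/choice sets and 100
replicates — sizes at which Monte-Carlo error is comfortably below the
assertion tolerances while the whole suite stays quick on one core.
Tie-breaks and edge rules are fixed and documented: strict inequalities
in both filters (a step exactly at the quantile or at 60 min is kept);
half-open bins with clamped overflow; +π in the last angle bin;
canonical-order tie-breaks for dominant-class labels; resting = state 1
on exact labeling ties. The pipeline writes a manifest (version, seed,
config, input hashes) and is byte-for-byte reproducible for a fixed
config and seed.

## Known limitations

- Per-individual fits share no information; rare classes retained for
  one individual but nearly constant for another can yield wide,
  prior-dominated intervals there.
- The four-alternative choice set approximates availability; no
  movement-kernel correction is applied beyond length matching, and no
  travel-time weighting of alternatives is used (with length-matched
  simultaneous alternatives such terms cancel from the conditional
  logit).
- The factorized categorical emission ignores step-angle dependence
  within a state.
- The coverage-ramp buffer rule is first-order accurate; at cell sizes
  much larger than the buffer it degrades (tests bound it at the 30 m /
  30 m and 10 m / 30 m geometries actually used).
- ASCII-grid raster I/O only; inputs must already share the telemetry's
  planar coordinate system.
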