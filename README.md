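# mosaicmove

Habitat selection and behavioural states from fixed-interval GPS telemetry
in fragmented ("mosaic") landscapes.

Animals tracked with GPS collars in human-modified landscapes reveal how
they cope with habitat loss: which land-cover classes they select or
avoid, where they slow down (a signature of resource use), and where and
when they rest. `mosaicmove` implements a reusable, fully testable
pipeline for this kind of analysis, built around the study design used
for giant anteaters in a pasture-dominated savanna mosaic: fixes every
20 minutes, a 30 m categorical land-use/land-cover (LULC) raster with six
classes (forest, savanna, wetland, *Eucalyptus* plantation, pasture,
mosaic of uses), and per-individual Bayesian model fits.

## What it computes

Each pair of consecutive fixes is a **step** with length *d*, duration
*t* and turning angle *θ*. After cleaning (top-1% step-length outliers,
gaps > 60 min, and — for the time model only — zero steps floored to
1 m), each step's path is buffered by 30 m and its LULC composition
*p* extracted from the raster.

**Time-explicit habitat selection (TEHS)** couples two submodels, fitted
per individual in a Bayesian framework:

- *time submodel* — log-normal regression of traversal time,
  `log t_i ~ N(β₀ + γ·log d_i + Σₖ βₖ p_ik, σ²)`, with pasture the
  baseline (implicit remainder). Reported as **time ratios**
  `exp(β_a − β_b)`: > 1 means slower movement (more time) in class *a*.
- *habitat-selection submodel* — conditional logit over the observed step
  and four cardinal (E/W/N/S) alternatives of identical length,
  `P(obs) = exp(α·p_obs) / Σⱼ exp(α·p_j)`. Reported as **odds ratios**
  `exp(αₖ)`: > 1 = selection over pasture, < 1 = avoidance. Population
  results are tallies of individuals whose 95% credible interval excludes
  1, stratified by sex.

**Behavioural states** come from a two-state (resting/active) hidden
Markov model with *categorical* emissions: step lengths binned at
0, 30, 60, 90, 120, 150, 180, 210, 512 m and turning angles in eight
equal bins on [−π, π], fitted by a custom Gibbs sampler
(forward-filter backward-sample states + conjugate Dirichlet updates,
1000 iterations, 500 burn-in). State labels feed **diel resting
profiles**: the proportion of resting steps per LULC class in twelve
2-hour bins of local time.

A synthetic-data module generates patchy landscapes and state-switching,
habitat-selecting trajectories with known parameters plus injected GPS
defects, so every stage is verified by parameter recovery — no animal
data needed.

## Worked example

```python
import mosaicmove as mm

run = mm.run_pipeline(
    {
        "seed": 5,
        "simulate": {"n_individuals": 2, "n_fixes": 350,
                     "sex_split": {"female": 1, "male": 1}},
        "tehs": {"n_iter": 400, "n_burn": 150, "n_chains": 2},
        "hmm": {"n_iter": 250, "n_burn": 100},
    },
    "runs/demo",
)
import pandas as pd
print(pd.read_csv(run / "diel_table.csv").head(3))
```

prints (abridged):

```
  lulc_class hour_bin   n  prop_resting  prop_resting_weighted  low_support
0     forest  [00-02)  19      0.473684               0.455337         True
1     forest  [02-04)  15      0.466667               0.440938         True
2     forest  [04-06)  19      0.473684               0.470895         True
```

i.e. in the `[00-02)` local-time bin, 19 forest-dominated steps were
observed of which 47% were classified resting (`prop_resting_weighted`
is the posterior-probability-weighted variant; `low_support` flags cells
with fewer than 20 steps). The run directory also contains the step
table with filter flags, buffered compositions, per-individual posterior
summaries, the time-ratio/odds-ratio records with their 95% CI verdicts,
population tallies by sex, per-step state probabilities, likelihood
traces, and a manifest making the run byte-for-byte reproducible.

The same stages are exposed on the command line:

```bash
mosaicmove simulate --out-dir data --seed 1
mosaicmove preprocess --in data/tracks.csv --out steps.csv
mosaicmove extract-lulc --steps steps.csv --raster data/landscape.asc \
    --legend data/legend.json --out comps.csv
mosaicmove fit-tehs --steps steps.csv --comps comps.csv --out-dir results
mosaicmove fit-hmm  --steps steps.csv --out-dir results
mosaicmove run-pipeline --config config.yaml --out-dir runs/full
```

Rasters are read as Arc/Info ASCII grids with a JSON code→class legend;
telemetry as Movebank-style CSV (planar `x`/`y` metres, or
`location-long`/`location-lat` which are projected to the UTM zone of
the track centroid).

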