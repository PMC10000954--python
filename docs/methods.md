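# Methods

## Problem and approach

`aoahg` performs *wrapper* feature selection on fixed-length embedding
vectors (for instance, the 128-dimensional penultimate-layer features a
convolutional network produces for medical images): the quality of a
candidate feature subset is defined as the hold-out performance of a
classifier trained on exactly those features, blended with a sparsity
term. The subset space is searched with a population of continuous
positions in the unit box, one coordinate per feature; a position is
decoded into a subset by thresholding each coordinate at 0.5 (strict
`>`). The searcher is a hybrid of two population metaheuristics:

- **AOA** (arithmetic optimization algorithm): per-coordinate
  divide/multiply exploration and add/subtract exploitation moves around
  the best-so-far solution, scheduled by two scalar curves — MOA, a
  linearly rising gate between search phases, and MOP, a decaying step
  scale `1 - t^(1/alpha) / T^(1/alpha)`.
- **HGS** (hunger games search): solutions accumulate "hunger" in
  proportion to their fitness gap to the best; hunger-derived weights
  W1 and W2 scale attraction toward the best solution, with a
  shrinking variation term R and an energy term `E = sech(|Fit_i -
  Fit_b|)` switching between approach and retreat.

The hybrid driver gates the two rule families per solution *and per
coordinate*: a uniform draw above MOA(t) takes an AOA divide/multiply
step (scaled by the dynamically shrinking per-dimension population
bounds through `(U - L)*mu + L`), anything else takes the hunger-weighted
step `W1*x_ij ± R*W2*|x_ij - xb_j|`. Because MOA rises with t,
arithmetic exploration dominates early iterations and hunger-based
refinement late ones. Plain-AOA and plain-HGS drivers with the identical
fitness protocol serve as ablation baselines.

## Objective

For a mask `BX` over `Dim` features,

    Fit = lambda * gamma + (1 - lambda) * |BX| / Dim,   minimised,

where `gamma` is the validation loss (1 − accuracy) of the back-end
classifier trained on the selected columns. `lambda` defaults to 0.99,
the common wrapper-FS weighting that makes one validation error worth
roughly two hundred features at `Dim = 128` — the subset-size term only
breaks near-ties in loss.

`gamma` uses a stratified 80/20 fit/validation cut of the training
partition, derived once from the run seed and frozen for the whole run,
so fitness is a deterministic, memoisable function of the mask and every
reported result replays exactly. Selected columns are standardised with
fit-fold statistics (RBF-SVM is scale sensitive). The empty mask never
trains a model; its fitness is pinned to 1.0, the top of the objective's
range, so empty solutions survive in the population but can never become
the incumbent.

## Parameters

| name | default | meaning |
|---|---|---|
| `min_acc`, `max_acc` | 0.2, 1.0 | MOA endpoints (dimensionless); standard values from the AOA literature |
| `alpha` | 5 | MOP sensitivity exponent |
| `mu` | 0.5 | scale constant in the arithmetic rules |
| `epsilon` | 1e-12 | stabiliser added to MOP in the divide rule and to SH in W1 |
| `lam` | 0.99 | loss-vs-sparsity weight in the objective |
| `l_hgs` | 0.08 | HGS self-perturbation branch probability threshold |
| `lh` | 100 | hunger lower bound LH |
| `pop_size`, `max_iter` | 50, 20 | evaluation protocol defaults |

All random draws (`r1..r6`, `rand`, the gates `Pi`, `PA`, `PH`) are
uniform on [0,1] from one seeded generator, so a seed fixes the whole
trajectory bit for bit. The multiplicative self-perturbation branch
`X*(1+rand)` therefore inflates by at most 2x before clipping; keeping
`rand` uniform (rather than Gaussian) keeps that branch bounded and is
the package's convention for every stochastic term. Draw granularity:
`R`'s inner draw and `r3..r5` once per solution per iteration; the
gates `Pi`, `PA`, `PH` per solution per coordinate. Hunger weights are
computed from the hunger carried into the iteration, *then* hunger is
accumulated, so in the very first iteration W2 is still zero and the
hunger branch is nearly inert.

Numerical conventions worth stating:

- `sech(x) = 2/(e^x + e^-x)` (i.e. `1/cosh`), giving `E` in (0, 1] with
  equality exactly at the best fitness.
- All updated coordinates are clipped to the fixed global box [0,1];
  the dynamic bounds of the population envelope feed only the
  `(U-L)*mu + L` scale of the arithmetic rules (and are recomputed once
  per iteration). Clipping keeps the 0.5 decoding threshold meaningful.
- Hunger's `UB - LB` factor is the mean bound range, so hunger is scalar
  per solution; with the unit box and `LH = 100` the floor branch
  `LH*(1+r)` is effectively always taken.
- Degenerate population (all fitnesses equal): the hunger increment `TH`
  is defined as 0, avoiding 0/0; every solution then matches the best
  and resets to zero hunger.
- Best-solution ties keep the first-found incumbent; the iteration
  counter is 1-based (`t = 1..T`).

## Synthetic data

The generator emulates deep-embedding datasets without any image input:
`n` samples, `dim` columns (default 128), near-balanced integer labels, a
random subset of `k` columns carrying class signal, the rest standard
Gaussian noise. Class-conditional means of the informative columns are
regular-simplex vertices — all pairwise centroid distances equal
`class_sep` — tiled across the k columns with random per-column sign
flips, so each informative column carries an equal share
(`class_sep/sqrt(k)` per column for two classes) and no single column is
dispensable by construction. Informative columns are jittered with
`noise_sd` (default 1.0, matching the noise columns' scale). A stratified
train/test split at `train_frac` (default 0.8; 0.7 and 0.85 are the other
protocol ratios) and the ground-truth mask are stored with the data.

What the generator does **not** emulate: correlated features (CNN
embedding coordinates co-vary), heavy class imbalance, label noise, and
distribution shift between training and test images. Passing tests on
this generator therefore demonstrate the mechanics and reproducibility
of the search, not clinical-grade performance.

## Behaviour on the study conditions, honestly measured

Three empirical properties of the printed update rules emerged from the
toolkit's own experiments (all reproducible via `tests/test_acceptance.py`
and `scripts/acceptance.py`):

1. **Validation-set overfitting.** With `lambda = 0.99` and a ~64-sample
   validation fold, the search can find masks whose validation loss is
   *lower* than the planted mask's (noise columns that happen to separate
   the validation points get selected). Recovery of planted columns is
   therefore structurally limited at these sizes: mean recall over seeds
   is near 0.5, not near 1, even when the search optimises its stated
   objective well.
2. **Pruning bias of the hybrid.** The multiply branch of the arithmetic
   rule maps a coordinate to `xb*MOP*scale`, which is below the 0.5
   threshold for most of the schedule, so the hybrid drifts toward small
   subsets; misses against the exhaustive optimum are usually subsets
   one validation error away with *fewer* features than the optimum.
3. **The hybrid is not uniformly the best minimiser.** The hybrid's
   arithmetic branch uses only the divide/multiply exploration rules, and
   its hunger step `R*W2*|x - xb|` vanishes as solutions approach the
   incumbent, so it lacks plain AOA's late around-best add/subtract
   refinement. On the 128-dim protocol plain AOA reaches lower mean
   wrapper fitness; the hybrid does beat plain HGS.

## Problem sizes

The shipped tests and the acceptance script run, as the package's own
protocol: exhaustive-oracle comparisons on an 8-feature/300-sample
instance over 10–20 seeds; the full-width protocol (128 features, 400
samples, population 50, 20 iterations, SVM fitness) over 5–10 seeds; and
a 3x4 optimizer-by-classifier benchmark on a 10-feature instance with a
reduced population. These sizes complete in minutes on one CPU while
exercising every code path at the protocol's population and iteration
counts.

## Known limitations

- Fitness uses a single hold-out fold, not cross-validation — fast and
  deterministic, but high-variance, which is exactly what drives the
  validation overfitting above.
- The exhaustive oracle is limited to 16 features (2^16 − 1 subsets).
- Only the three shipped optimizers are implemented; other published
  metaheuristics (PSO, GWO, ...) are out of scope.
- Multiclass precision/recall/F1 are support-weighted by default; macro
  averaging is available but per-class tables are not produced.
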