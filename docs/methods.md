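# Methods

## Circuit model

A circuit is a signed directed graph of transcription factors.  Node levels
follow

    dX_i/dt = g_i * prod_{j->i} H(X_j; B0_ji, n_ji, lam_ji) - k_i X_i

with the shifted Hill term `H(B) = lam + (1-lam)/(1+(B/B0)^n)`: 1 with no
regulator, `lam` at saturation.  Regulators acting on the same target
combine multiplicatively; activators carry `lam > 1`, inhibitors the
reciprocal of a sampled fold change (`lam = 1/lam_raw`, so typical
inhibition is strong).  Activator terms are deliberately *not* rescaled by
their fold change (a normalization some ensemble frameworks apply so that
`g` is the maximal rather than basal rate); with the threshold rule below,
the unnormalized form is the variant that reproduces the reference state
statistics of the packaged circuit.

The packaged default is the three-gene SMAD3–KLF4–PPARG network observed to
govern E/M state dynamics in bladder carcinoma lines: mutual inhibition
SMAD3 ⊣ PPARG ⊣ SMAD3 (a toggle switch), mutual activation SMAD3 ↔ KLF4,
PPARG → KLF4, and self-activation on all three nodes.

## Random-parameter ensemble

One "model" is a random draw of kinetic parameters; the ensemble
characterizes what the *topology* allows rather than any single
parameterization.  Sampling ranges (arbitrary units):

| parameter | range | note |
|---|---|---|
| production g | U(1, 100) | per node |
| degradation k | U(0.1, 1) | per node |
| fold change lam_raw | U(1, 100) | per edge; inverted for inhibitors |
| Hill coefficient n | integers 1..6 | per edge |
| threshold B0 | U(0.02, 1.98) × M_src | half-functional rule |

**Half-functional thresholds.** `M_src` is the median level of the edge's
source node, estimated by a one-step Monte Carlo: the unregulated level
g/k multiplied by the shifted-Hill factor of each of the source's own
in-links, with regulator levels drawn from unregulated distributions and
inner thresholds centred on the unregulated median (~114 for the default
ranges).  This keeps each regulation dynamically relevant for a substantial
part of the ensemble even for nodes whose levels are inflated by activator
fold changes (KLF4, with three activators, has a one-step median near
2×10^5) or depressed by inhibitors.  The estimate uses a fixed internal
seed so thresholds do not vary with the run seed, and is cached per
(topology, ranges).

**Integration.** Euler steps (h = 0.05) to T_max = 200 time units from 100
initial conditions per model, log-uniform on [0.01, 100·g_max/k_min].
A trajectory stops early once the residual satisfies
`||dx/dt||_inf <= 1e-6 * max(1, ||x||_inf)` (after a minimum of 400 steps,
which avoids stopping on slow transients); non-converged trajectories
(including oscillatory models) are counted and excluded.  Endpoints are
deduplicated per model at 1 % relative infinity-norm tolerance, keeping at
most 10 states per model, and every retained state is by construction a
verified root of the right-hand side.  The inner loop is a numba kernel
with integer-exponent Hill evaluation; a 2000-model run takes ~10 s on one
CPU.

**Z-scores and classification.** Levels are log2-transformed (offset 1e-9
guards exact zeros) and z-scored per node with the population-SD
convention.  Each state is assigned to a quadrant by the signs of z(PPARG)
and z(SMAD3): E = (+,−), M = (−,+), DN = (−,−), DP = (+,+); points exactly
on a boundary count as "low".  Fractions weight each distinct state by its
basin multiplicity — the number of initial conditions that converged to it —
which is equivalent to pooling the endpoint of every initial condition.
An unweighted distinct-state mode is available
(`classify_states(..., weighted=False)`); the weighted basis is the default
because it is the sampling a one-endpoint-per-model pipeline produces and
it reproduces the reference fractions for the default circuit.

**Perturbations.** Over-expression multiplies the perturbed node's sampled
production rate by the fold (default 20), down-expression divides; all
other draws, including thresholds, reuse the control sampling (same seed),
so a perturbed run differs from control only in that node's production.
Perturbed states are z-scored with the *control* mean/SD, making fractions
directly comparable to control.

**Reference behaviour and a known trade-off.** At these conventions the
unperturbed default circuit yields ≈61 % E, ≈17 % M, ≈17 % DN, ≈4 % DP
(2000 models), and the perturbation panel responds in the expected
directions: PPARG-OE raises E to ≈86 %, PPARG-DE collapses it to ≈8 %,
SMAD3-OE raises M to ≈60 %, KLF4-OE to ≈36 %, KLF4-DE lowers it to ≈12 %.
A grid exploration of per-node threshold scales (the main free convention)
shows a structural tension in this model family: configurations that make
the SMAD3/KLF4 links half-functional in the realized ensemble produce much
stronger SMAD3/KLF4-OE responses but destroy the E-dominant control
composition, and vice versa.  The shipped defaults favour the control
composition; the magnitude of SMAD3/KLF4 over-expression responses is the
corner of the panel this family reproduces least well.

## Synthetic live imaging

The generator emulates time-lapse microscopy of labelled colonies, not any
particular instrument.  Cells live on a 1000×1000-unit plate (≈ one
15-mm well, so 1 unit ≈ 15 µm) imaged every 2 h.  Per interval each live
cell independently: dies (class-specific probability, default 0), divides
(default 0; the daughter inherits the label and appears beside the mother),
switches label per the 2×2 row-stochastic matrix built from `p_me`/`p_em`,
then takes an isotropic Gaussian step (default SD 2 units/interval ≈
30 µm/2 h, mid-range for carcinoma cell motility at this plate scale)
reflected at the plate boundary.  Death is recorded as a final
`alive=False` row; lineage (parent id) is kept throughout.

Morphology features (radius, area, perimeter, solidity, formfactor,
eccentricity, compactness) are drawn from class-conditional distributions:
independent Gaussian latents pushed through exp (sizes) or logistic
(bounded descriptors).  The `separation` parameter is the class-mean gap in
latent SDs on every feature, signed so M cells are smaller, rounder, more
solid and compact, E cells larger, flatter, more eccentric; separation 0
makes the classes identical, separation 3 makes them almost perfectly
linearly separable.  Units are arbitrary — no claim of matching real
image-cytometry pipelines.

The scratch-wound scenario removes all cells inside a vertical band from a
confluent monolayer, then simulates migration-only dynamics with a
class-specific drift toward the band centre plus noise.  Occupancy per
frame is the percentage of band pixels (4-unit raster) within a 10-unit
footprint radius of an *in-band* cell centre, so an intact monolayer
hugging the scratch edge scores 0.

What passing tests on this generator do **not** show about real data:
there are no cell–cell mechanical interactions, no density-dependent
growth, no label misclassification noise, no drift in imaging conditions,
and switching is time-homogeneous.  Estimator performance here is an upper
bound on real-data performance.

## Transition-rate estimation

The plate is tiled with half-open square grids (default sizes 1/8, 1/4 and
1/2 of the plate side, anchored at the plate origin; boundary points go to
the higher-index cell).  For each consecutive frame pair and grid size, the
per-grid M-proportions `m_g(t)` enter the constrained least squares

    min_{a,b in [0,1]}  sum_g w_g [ m_g(t)(1-a) + (1-m_g(t))b - m_g(t+1) ]^2

for a = P(M→E), b = P(E→M); rows are weighted by sqrt of grid occupancy
(binomial noise ∝ 1/n) and grids need ≥ 5 cells at both frames.  Intervals
whose design is rank-deficient — e.g. every grid pure single-class at the
earlier frame — are reported as underdetermined and skipped by the
pipeline.  Per-interval estimates are aggregated into mean ± SD per ordered
pair, stratified by grid size and pooled, weighting each estimate by the
number of grids that informed it; the SD uses the sample (n−1) convention.

Three further modes exist because the estimator landscape is genuinely
subtle:

- **Unconstrained per-pair regression** (`mode="unconstrained"`), for
  comparison with rate tables reported without the simplex constraint
  (whose rows need not sum to 1).
- **Pooled constrained estimation** (`estimate_transitions_pooled`):
  stacks all intervals and grid sizes into one regression.  Within a
  single interval all grids share the same expected composition, so the
  per-interval design is macroscopically rank-1 and both probabilities are
  identified only through finite-population fluctuations, whose
  signal-to-noise ratio does not improve with cell count; pooling
  intervals at different compositions restores consistency.  The
  convergence property tests use this mode.
- **Track-based maximum likelihood** (`estimate_transitions_tracked`):
  counts label flips along cell identities.  An oracle for synthetic data;
  real grid-based imaging does not support it.

Known limitation: cell migration exchanges cells between grids within an
interval, which attenuates the per-grid regression signal and leaves a
small bias (order 0.01–0.03 at the default motility) that does not vanish
with cell count.  The default motility and grid sizes keep it well inside
the dispersion of the per-interval estimates.

## Morphology classification and summaries

`classify_morphology` standardizes the seven features, projects onto the
first two principal components and splits observations by 2-means; the
cluster with the smaller mean area is called M.  The mapping is
data-driven (no dependence on cluster indices), invariant to per-feature
rescaling and observation order, and deterministic under a seed.  Degenerate
inputs (fewer than two observations, constant feature matrix) are errors.

`clonal_efficiency(observed, seeded) = 100·observed/seeded`; more colonies
than seedings warns (merging/counting artifact) but returns the value.
`wound_closure` linearly interpolates band occupancy between frames and
refuses times outside the assay horizon.

## Reproducibility

Every stochastic component takes a seed or `numpy` Generator; identical
seed and configuration give bitwise-identical solution tables, track
tables and fraction tables.  The acceptance script
(`scripts/acceptance.py --seed N --out results/acceptance.json`) derives
all of its randomness from the single command-line seed and uses
4000-model ensembles and 2000-cell track simulations — sizes at which the
reported fractions are stable to about one percentage point and the
recovered transition probability to about ±0.04.
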