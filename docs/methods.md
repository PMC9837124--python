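# Methods

## Scope and model structure

`peatfire` couples a daily soil-column water balance to a fortnightly
fire-count regression. Grid cells are *stand-alone*: they never exchange
water with their neighbours, and each cell's only hydrologic link to the
wider landscape is a fixed lateral boundary water table (WTDx). This
keeps each cell an independent one-dimensional problem and makes grid
runs embarrassingly parallel, at the cost of neglecting upland-to-coast
lateral recharge (see limitations).

A column is an ordered stack of soil layers (15 by default, top two
0.03 m thick) beneath a 0.02 m litter mat. Each layer carries thickness,
dry bulk density, organic-matter fraction, van Genuchten retention
parameters (θr, θs, α, n) and a saturated conductivity. A layer is peat
when its organic-matter fraction exceeds 0.65; a cell is a *peatland
grid* when every layer down to at least 0.3 m is peat.

## Water balance

Each day is integrated in 24 sub-steps. Per sub-step, in order:

1. **Precipitation** enters a surface ponded store.
2. **Infiltration** moves ponded water into the litter and then the soil
   top-down, each layer filling at most to θs, with the flux through
   layer *i* throttled by the minimum saturated conductivity of the
   layers traversed.
3. **Evapotranspiration.** Potential ET is a Penman–Monteith-style daily
   reference value (net radiation approximated as 0.77·Rs − 2 MJ m⁻² d⁻¹,
   soil heat flux neglected) scaled by a land-cover coefficient
   (0.9–1.05). Water is taken first from the ponded store and litter
   (unstressed), then as transpiration from the top 0.5 m under a linear
   stress ramp between the wilting point (1.5 MPa ≈ 153 m suction head)
   and field capacity (3.3 kPa ≈ 0.34 m).
4. **Vertical drainage** is a tipping bucket: moisture above field
   capacity drains downward at a rate bounded by the Mualem unsaturated
   conductivity k(θ) = Ksat·√Se·[1−(1−Se^{1/m})^m]² and by the acceptance
   capacity of everything below (computed bottom-up, so saturation backs
   up correctly). The column base is closed; water leaving the profile
   does so laterally or by ET.
5. **Lateral exchange** is Darcy flow against the boundary water table:
   q = K̄·(WTDx − WTD)/L per day, with K̄ the mean saturated conductivity
   of the saturated layers and L the lateral flow distance (default
   100 m). Positive q discharges water out of the column, draining first
   the partially saturated transition layer and then the saturated zone
   top-down, each tapped layer resting at field capacity; negative q
   recharges the column from the bottom up. Draining the transition layer
   first prevents a rain-percolation artefact in which the diagnosed
   water table transiently rises and triggers discharge that overshoots
   the boundary equilibrium.
6. **Runoff** removes ponded water above a 0.02 m ponding limit.

The flux ledger P − ET − lateral − runoff − ΔS closes to machine
precision by construction; the tests enforce ≤ 10⁻⁶ m on 1,000 random
daily steps.

**WTD diagnosis.** The water table is the depth above the
bottom-contiguous saturated zone (layers with θ ≥ 0.999·θs). Inside the
deepest unsaturated layer the depth is interpolated linearly between
field capacity (no contribution) and saturation, so WTD moves
continuously instead of jumping between layer boundaries. A fully
saturated or ponded column reports 0; a column with no saturated base
reports its total depth. Exports carry both sign conventions; internally
WTD is positive downward.

**Near-surface moisture** is the thickness-weighted mean over the litter
and the top two soil layers (0–5 cm). The two top layers are 0.03 m
*each*; an alternative reading (0.03 m combined) would simply re-weight
the same inputs and is not exposed.

**Spin-up** repeats the first forcing year until the annual-mean WTD
drifts by less than 1 mm between cycles, up to 56 cycles, each cell
exiting independently. Initial states are pre-saturated below WTDx, so
peat cells typically converge in a few cycles; deep mineral columns may
use the full budget.

**Numerics.** The day/sub-step loops are compiled with numba; cells are
advanced in an outer per-cell loop, so outputs are bit-identical under
cell reordering and to single-cell runs. The scheme is explicit;
halving the sub-step changes the WTD after a rainy fortnight by less
than the configured 0.02 m tolerance. A single daily step (sub_steps=1)
is materially coarser and not recommended.

## Boundary water tables and land use

Non-peatland grids (except mangroves) drain to a 6 m boundary,
permitting discharge along the whole profile. Mangroves sit at 0 m
(tidal; no artificial drainage — these cells are otherwise out of
scope). Peatland boundaries encode drainage intensity by land use:
pristine forest 0.30 m, degraded forest 0.35 m, industrial plantation
0.60 m, smallholder farmland 0.75 m. The values are configurable; the
defaults were chosen so that the drainage-intensity ordering
forest < plantation < smallholder — the ordering reported from field
observations — emerges in simulation, and the simulated means on the
default synthetic year (≈ 0.25/0.28, 0.44, 0.55 m) do.

## Retention fitting and pedo-transfer

`fit_retention` least-squares fits (θr, θs, α, n) to (ψ, θ) samples with
`scipy.optimize.curve_fit` under box bounds (θr below the driest sample,
θs above the wettest, α ∈ [10⁻³, 10²] m⁻¹, n ∈ (1, 10]); at least four
distinct suctions spanning wet and dry conditions are required.
Noise-free samples recover parameters to < 1 %; 1 % multiplicative noise
keeps mean recovery error < 10 % over 100 seeds.

Saturated conductivity defaults to log-linear pedo-transfer functions of
bulk density, clamped to [0.001, 50] m d⁻¹: peat Ksat = 10^(2.2 − 14·BD)
(12 m d⁻¹ at BD 0.08, 0.25 m d⁻¹ at BD 0.20), mineral
Ksat = 10^(1.2 − 1.0·BD). Both are overridable per layer via the profile
CSV; lateral conductivity is taken equal to vertical.

## Fire models

Both variants share one architecture: input (6 or 8 nodes) → 32 relu →
16 relu → 1 linear, mean-squared-error loss, Adam at learning rate
0.001, early stopping. Training is leave-one-year-out: for each calendar
year a network is fitted on the remaining years and predicts the
held-out year, so every record receives exactly one out-of-sample
prediction. Features are z-scored with training-fold statistics only.
Raw outputs are clipped at zero (counts are nonnegative).

Implementation is `sklearn.neural_network.MLPRegressor`. Early stopping
holds out a random 10 % of the training rows (sklearn's internal split —
not stratified by year), patience 20 epochs, at most 500 epochs, batch
size 256. One pooled model is trained over all cell-level rows rather
than one network per cell: per-cell fortnight counts are small and
noisy, and at desk scale a pooled model is the better-identified choice;
per-cell training can be emulated by filtering the records table.

Evaluation pools predicted and observed counts per fortnight over
peatland and non-peatland subsets before computing R² = 1 − SSres/SStot
and MAE, plus both statistics on first differences n_{t+1} − n_t (timing
skill). The fire-occurrence water-table threshold is the candidate depth
(0.00–1.00 m, 0.01 m grid) maximising Youden's J = sensitivity +
specificity − 1 for the rule "fire when mean WTD ≥ depth", ties broken
shallow; a maximum J below 0.1 is flagged uninformative. A "fire event"
is a cell-fortnight with at least one count — the generator's occurrence
process makes any stricter quantile definition a configuration choice,
not a different estimator.

## Synthetic study setting

The generator emulates an equatorial peatland province at desk scale:

- **Rainfall**: per-day Bernoulli wet/dry with seasonal wet probability
  (0.65 base; 0.30 in the short dry window, days 15–59; 0.15 in the long
  window, days 166–298) and gamma wet-day amounts (mean 14 mm, shape
  0.9) — about 2,170 mm yr⁻¹ in a normal year. Drought years (defaults
  2012 and 2015 of the 2008–2015 study window) scale the wet-day
  probability by 0.6. Temperature, radiation, humidity and wind co-vary
  with the seasonal dryness so dry spells are warmer, sunnier and drier.
- **Soils**: a 1.5 m, 15-layer peat archetype (BD 0.08→0.18 down-profile,
  OM 0.90, θs ≈ 0.84–0.90) and a 3.0 m mineral archetype (BD 1.15→1.50,
  OM 0.05, θs 0.45), with ±10 % seeded bulk-density jitter per cell;
  60 % of cells are peat, split 25/15/35/25 % among pristine forest,
  degraded forest, industrial plantation and smallholder use.
- **Fire counts**: per cell-fortnight, counts ~ Poisson(λ) with
  λ = λmax · σ((WTD − d*)/s) · dryness(θns), d* = 0.40 m, width
  s = 0.015 m, λmax = 6, and dryness ramping linearly from 0.05 (wet,
  θns ≥ 0.85) to 1 (dry, θns ≤ 0.25). The small width makes occurrence
  nearly threshold-like. It also keeps the Youden-J estimate close to
  d*: the J-optimal cut sits where P(event | WTD) crosses the marginal
  event rate, i.e. within a few widths of d*, so the design bias
  (≈ 0.03–0.05 m shallow) stays inside the recovery tolerance.
- **Observations**: moisture observations are truth + iid N(0, σ²)
  clamped to [0, 1]. With σ equal to the signal standard deviation the
  expected correlation is 1/√2 ≈ 0.707, which the tests check as a
  median over 50 cells.

What the generator does **not** emulate: spatial rainfall
autocorrelation, coastal tidal recharge, observation biases with
structure (the synthetic "satellite" noise is white), land-use change
over time, and haze/suppression feedbacks on fire detection. Passing
tests therefore demonstrate internal consistency and mechanism recovery
— not skill on real reanalysis/satellite data.

## Problem sizes and runtime

Default experiment scale is 50 cells × 8 years (2008–2015), which a
single CPU simulates in ~5 s after JIT compilation; the ten-seed
threshold-recovery experiment takes about a minute, and the ten-replicate
model-contrast experiment a few minutes (dominated by network training).
Skill-contrast replicates share one simulated hydrology and vary the
Poisson count draw and network seeds — hydrology is deterministic given
forcing, so re-simulating per replicate would only add runtime.

## Known limitations

- Tipping-bucket vertical flow has no capillary rise; prolonged
  dry-season near-surface moisture is therefore controlled by ET depth
  and litter rewetting, not matric redistribution from the water table.
- The simplified reference-ET formula ignores day length/latitude in net
  radiation; PET magnitudes are plausible (~4–5 mm d⁻¹) but not
  site-calibrated.
- The lateral exchange collapses all boundary geometry into a single
  conductance K̄/L; real canal networks have stage dynamics.
- Mangrove cells are carried with a surface boundary but tidal dynamics
  are out of scope.
- The LOOCV networks are pooled across cells (see above); per-cell
  training at the original study's grid scale would need far more data
  per network than the synthetic benchmark provides.
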