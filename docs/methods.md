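# Methods

This note documents the models implemented in `peakshift`, the choices made
where the design was genuinely open, and what the synthetic chamber emulator
does and does not capture.

## Thermal-time flowering model

An inflorescence carries up to `flw_limit = 7` flowers opening sequentially.
Development is a pure function of daily mean temperature `T(t)` (°C):

    d_b(t) = T(t) / CT_ff · (flw_limit − 1),      CT_ff = 252.1 °C·day

`CT_ff` is the cumulative temperature needed to progress from the 1st to the
7th flower. The cumulative index `B(t) = Σ_{τ=t0..t} d_b(τ)` accumulates from
the observed first-flowering date `t0` **inclusive** (the first-flowering day
contributes — the literal reading of the sum), and flower *j* (j = 2..7)
opens on the earliest day with `B(t) ≥ j − 1`. Consequences of the inclusive
bound: at a constant 19 °C the 2nd flower opens 2 days after the first and
the 7th after 13 days; in the degenerate unit-increment case (`d_b` = 1/day)
flower *j* opens `j − 2` days after the first.

Numerical choices: dates are whole days everywhere (inputs are daily means);
negative daily means contribute zero development (biological floor, never
exercised by the operating range 8.65–18.19 °C); thresholds not reached by
the end of the temperature series are reported as unresolved, never dropped
silently. Observed flowering dates always override predictions.

## Maturation models

**Thermal threshold (default).** A fruit is harvest-ripe on the first day the
daily mean temperatures, summed from the day *after* flowering, reach a heat
threshold (default 600 °C·day — the classical accumulated-temperature rule
for strawberry). The half-open convention keeps 600 °C·day / 15 °C = exactly
40 days. Two properties matter to the controller and are asserted by tests:
raising every future temperature never delays harvest (monotonicity), and
scaling threshold and temperatures together leaves the date unchanged.

**Stage regression (pluggable).** The flowering→harvest period splits into
four stages (flowering, green, white, turning); each stage's duration is a
user-supplied function `ND_i(AT_i)` of the mean air temperature over that
stage. Because `AT_i` depends on the stage's own unknown duration, each stage
is solved by fixed-point iteration: start from the duration implied by the
entry-day temperature, recompute the stage-mean over the implied window,
repeat to a 0.5-day tolerance with a 20-iteration cap (non-convergence is an
error, not a silent fallback). Supported duration families: `constant`,
`linear`, and `reciprocal_linear` (`a / (AT − b)`), each validated to return
≥ 1 day over 5–30 °C. The published stage coefficients for strawberry live in
earlier ripening literature and are **not** bundled; any coefficients in the
examples are illustrative only. Observed harvest dates always override
predictions (this replacement is what pins the predicted peak to reality as
the season progresses).

## Population harvest distribution

With 7–14 plants the raw daily harvest counts are too sparse for a stable
peak. Each fruit contributes one Gaussian kernel centred on its effective
(observed-else-predicted) harvest date with a fixed σ = 14.34 days, an
empirically calibrated constant treated as opaque and configurable. Kernels
are normalized densities evaluated pointwise at integer days (the
bin-integration correction is O(σ⁻²) and negligible at this σ), summed
across fruits; the curve integrates to the fruit count to ~1e-9 per fruit on
a ±6σ grid.

The **peak** is the grid date with the maximum value; ties break to the
earliest date (deterministic, and biased against overshooting the target).
The **FWHM** is computed by the literal above-half rule on the daily grid:
last minus first day strictly above half the maximum, no sub-day
interpolation. On the daily grid a single kernel measures 32 days; the
continuous-limit closed form 2√(2 ln 2)·σ = 33.77 days is recovered on a
fine grid (`mixture_fwhm`). Flowering-count distributions reuse the same
estimator with flowering dates as centers.

## Feedback offset controller

Error signal: `Δd = predicted peak − target` (days, positive = late). At
each update the controller exhaustively evaluates all 101 candidate offsets
ΔT ∈ [−5, +5] °C (0.1 °C grid, both endpoints included) by re-running
phenology → maturation → distribution with temperatures equal to the
realized past (baseline + applied offsets) up to the current date and
baseline + candidate ΔT from the current date to the horizon. Selection:
minimize |Δd| (exact Δd = 0 preferred), then minimize |ΔT|, and a final tie
goes to the cooling side (cooling showed no quality penalty while heating
reduced soluble solids). The tie-break chain is total, so the search is
deterministic. Heating (ΔT > 0) is chosen when the peak is late — the sign
follows from maturation monotonicity, nothing is hard-coded.

The chosen offset takes effect **on the update day itself** and is held
piecewise-constant until the next update; the emulator is advanced only
through the previous day before each search. This alignment matters: if the
update day is realized under the stale offset while the search assumes the
new one, a one-day actuation error accrues at every offset change and
perfect-model convergence visibly degrades. Updates continue after the
target date exactly as scheduled (matching the campaign's practice); a
`stop_after_target` flag implements the proposed termination rule and
defaults off. The candidate-evaluation horizon defaults to the season end
and is configurable.

## Chamber emulator

The emulator is the synthetic stand-in for the climate chamber plus plants.

**Baseline temperatures.** The pre-period (flower promotion, until virtual
Nov 14) is fixed at 19 °C. The regulation segment (Nov 14 – Jan 31) is a
declining linear trend (3 °C across the window) plus AR(1) noise (φ = 0.7),
affinely rescaled to mean 13.62 °C / SD 1.99 °C and clamped to
[8.65, 18.19] °C — the published summary statistics of the reproduced
greenhouse season; the original series itself is unpublished. Clamping
touches ~1–2 % of days, so the post-clamp moments stay within the tested
tolerances (±0.2 °C on the mean, ±0.3 °C on the SD). Deterministic per seed.

**Scenarios.** CL/HT/CT map to peak shifts of −7/+7/0 days against the
reference peak (virtual Dec 21). The first-flowering date is back-calculated
by scanning candidate dates and forward-simulating a zero-noise plant until
the uncorrected population peak lands on the shifted reference — mirroring
the campaign's back-calculation of each plot's pre-shift initial conditions
from its predicted peak. The shift is applied in peak space deliberately:
the warm pre-period makes the flowering→peak map nonlinear, so shifting
first flowering by ±7 days would not shift the peak by ±7 days.

**Plants.** The chamber advances one day at a time. Each day applies
baseline + schedule offset, accumulates every plant's inflorescence
development and every flowered fruit's post-flowering heat sum under the
temperature actually in force, and reveals events once their date is reached
(daily visual inspection). Ground truth uses the same thermal-threshold
family as the predictor; a zero-noise run is therefore a perfect-model loop
isolating controller behaviour from model error. Plant variability defaults:
first-flowering jitter SD 2 days (plant-to-plant asynchrony a grower would
expect), per-fruit maturation jitter SD 1.5 days; `perfect_model()` zeroes
both. Ground-truth stage-regression maturation is not emulated (the
incremental chamber supports the threshold family only); the predictor side
supports both.

**Record slots.** The emulator exposes one fruit-record slot per potential
flower (1..7) per plant. Slots beyond the scenario's `fruits_per_plant`
never bloom, while a prediction-side simulator always models the full
complement — reproducing the real failure mode in which cooling control
breaks down because forecasts count on later-blooming flowers the plants do
not deliver (with 3 fruits/plant the loop ends 6–7 days early versus 0–1
days for the full population on the same seed).

**What the emulator does not capture.** Radiation, photoperiod, humidity and
CO₂ dynamics (constants 70 % / 400 ppm), plant carbon balance, fruit
size/mass dynamics, cultivar differences, and spatial heterogeneity. Passing
closed-loop tests therefore demonstrate controller correctness under the
stated thermal-time model family, not field performance.

## Quality statistics battery

Derived metrics follow the shipment standards: DM ratio = 100·dry/fresh (%);
weight grades with strict lower bounds 3L (> 23 g), 2L (> 18 g), L (> 14 g),
M (> 10 g), S (> 6 g), nonstandard (≤ 6 g) — a boundary weight falls to the
lower grade; premium ratio = %KJ, marketable ratio = %(KJ+B).

Continuous traits: Shapiro–Wilk per group at α = 0.05 (the gate's α is not
stated in the source protocol; 0.05 is the conventional choice); both normal
→ one-way ANOVA with a Tukey-HSD pairwise decision (coincident with the
F-test for two groups), otherwise two-sided Mann–Whitney U. Constant-valued
groups have undefined normality and fall to Mann–Whitney with a warning.

Grade tables: Pearson χ² (no continuity correction, df = grades − 1 for two
groups) plus per-grade **pooled-variance** two-proportion z-tests with
Bonferroni correction over the tested grades (p_adj = min(1, m·p)). Pooled
rather than unpooled variance is deliberate: on the bundled reference
tables pooled reproduces the published z = −2.04 for the 3L band, unpooled
gives −2.08. Nonstandard fruits are excluded from the tested bands, and
zero-margin grades are dropped with a warning. Class ratios use the same
pooled z-test without correction.

The bundled reference tables (`peakshift.datasets`) are the unique integer
reconstruction of the published percentage tables given the group totals
(CL 80, HT 91, CT 83) — every printed percentage is an exact count. Known
inconsistency in the source material: the continuous-trait table reports
CL n = 76 while the grade table implies 80; the package carries the counts
that reproduce the printed statistics and takes no side.

## Problem sizes and verification

The default study conditions are 14 plants × up to 7 fruits (98 fruits per
chamber), one virtual season (Oct 1 – Jan 31), 9 update dates, 101-candidate
search. The acceptance script runs the two ±7-day perfect-model scenarios at
these sizes (~2 s each). The test suite additionally runs 20 seeded noisy
loops, 200-series brute-force oracle sweeps, 50-seed baseline statistics,
and a 50-state exhaustive-search cross-check; everything it asserts is
computed at run time by the code under test.
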