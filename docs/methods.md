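# Methods

This note documents the models behind the three simulation experiments, the
parameters that matter, the numerical choices, and what the synthetic setups
do and do not show about real archaeological data.

## Calendar conventions

Time is a signed integer year axis: BCE years are negative (1750 BCE →
−1750) and time increases toward the present. No year-zero adjustment is
made — the axis is purely arithmetic, which keeps interval arithmetic and
binning trivial. All intervals (phases, histogram bins, mine use-lives) are
half-open `[start, end)`, so contiguous phases partition the window with no
double counting. Calendar years BP are related by `BP = 1950 − year`;
helpers convert in both directions.

## Chronological uncertainty and aoristic redistribution

Three layers of dating uncertainty are represented:

* **phase assignment** — an event carries a probability vector over
  candidate phases (a point mass when the label is certain);
* **within-phase position** — uniform by default, or a trapezium density
  with corners a ≤ b ≤ c ≤ d (linear rise on [a,b], flat top of height
  h = 2/((c+d)−(a+b)) on [b,c], linear fall on [c,d]); with a=b and c=d it
  degenerates to the uniform distribution, which is the default because the
  periodization experiment assumes uniform within-phase uncertainty;
* **phase boundaries** — the trapezium corners can be jittered inside
  user-supplied intervals between Monte Carlo repetitions (draws violating
  the corner ordering are rejected and redrawn). No published numeric ranges
  exist for boundary uncertainty, so the widths are configuration, not
  defaults derived from data.

Trapezium sampling uses the closed-form inverse CDF (piecewise: square root
on the ramps, linear on the top), so samples are exact and cheap. A
degenerate trapezium with a = d is rejected rather than treated as a point
mass: a point mass is not a density, and permitting it would silently break
the interval-probability contract.

`mc_aoristic` re-simulates a calendar year for every event (phase from its
probability vector, then year from the within-phase model), bins the years,
and repeats `n_sim` times. Each repetition places every event exactly once,
so every row of the output matrix sums to the event count — redistribution
can distort timing but never invents or destroys mass. The envelope reports
the per-bin mean and a 2.5–97.5 percentile band by default.

## Periodization experiment

The true history is a logistic intensity per year,
`floor + (ceiling − floor) · logistic(rate · (t − t_mid))`, over the window
[−800, −300). The published description fixes the shape (logistic growth
within 600–500 BCE) but not the constants; the defaults here are
t_mid = −550, rate = 0.1/yr (so the transition effectively occupies that
century), floor:ceiling = 1:10, n_events = 1000, 50-year bins, 1000 Monte
Carlo repetitions. Events get integer years sampled ∝ intensity, are
stripped to phase labels, reconstructed with `mc_aoristic`, and compared
with the true binned counts via per-bin RMSE plus the signed error in the
bin of maximum true growth.

Because a logistic rise is nearly a step function, the best two-phase
slicing puts its boundary at the transition midpoint — uniform
redistribution within "before" and "after" phases then reproduces the trend
almost exactly. Phase boundaries far from the change bury the growth
mid-phase and smear it; a single phase erases the trend entirely, leaving a
flat envelope at n/n_bins. The shipped presets (`two_at_transition`,
`three_bracketing`, `two_mismatched`, `three_mismatched`, `single_phase`,
`five_fine`) span that design space; they are labelled as approximations of
the design space, not reproductions of any published panel, whose exact
boundaries were never printed.

## Duration experiment

A fixed count of `n_active = 100` mines is maintained over [−1750, −750):
every abandonment triggers an immediate replacement, so exactly 100 mines
are in use in every one of the 1000 years by construction. The expected
use-life of a mine founded at year t declines linearly from 200 years at
−1750 to 10 years at −750 (clamped outside). Individual durations are
`1 + NegBin(mean = μ(t) − 1, size = k)` — the shift makes the analytic mean
exactly μ(t) and a zero-length use-life impossible, and the negative
binomial is the standard overdispersed waiting-time-to-failure model. The
dispersion k is not printed anywhere; the default k = 2 gives strong
use-life variability (CV ≈ 0.7 at the window start) and is recorded in the
run metadata.

All 100 slots are founded at the window start (the initial age structure is
otherwise unconstrained). This creates a start-up transient in the naive
count — the first century bin undercounts turnover because no mine can have
been founded before −1750 — so trend statements skip the first bin, and
records still open at −750 are truncated there, preserving total mine-years
exactly.

The *naive* count tallies each mine once in every bin its use-life
intersects, however briefly: the count an observer makes when duration is
unknown. Under the declining-duration model it roughly quintuples across
the millennium while true occupancy never moves.

Dating emulation: 15 mines are selected — the 5 founded nearest each of
three target years (−1700, −1250, −800; a mine can serve only one target) —
and each yields 5 calendar years uniform over its use-life, converted to
simulated ¹⁴C determinations.

## Radiocarbon model

A calibration curve is a table (calendar age BP, ¹⁴C age BP, 1σ), linearly
interpolated; queries outside the tabulated range are rejected rather than
extrapolated. *Back-calibration* draws the measured age from
N(μ(calBP), √(σ_curve² + σ_lab²)), rounded to integer ¹⁴C years; defaults
σ_lab = 25 and σ_curve = 10 ¹⁴C years are typical lab/curve magnitudes and
are configurable. Single-date calibration evaluates that Normal likelihood
on the integer-year grid and normalizes.

The synthetic plateau curve is identity on the old side, constant across a
chosen calendar interval, and identity shifted by the plateau width on the
young side — continuous at both joins. This reproduces the mechanism of a
real calibration plateau (such as the one spanning roughly 800–400 BCE):
every calendar year across the plateau predicts the same ¹⁴C age, so a
single date calibrates to the full plateau width and phase spans estimated
from plateau dates are systematically inflated.

The span model is a uniform-phase Bayesian model: an episode occupies an
unknown interval [s, e]; each date's true year is Uniform(s, e); the
marginal likelihood is L(s,e) = Πᵢ [ ∫ₛᵉ ℓᵢ(t) dt / (e−s) ] with ℓᵢ the
calibration likelihood. The posterior is evaluated exactly on an (s, e)
grid (default 5-year step — ≤ ~40k cells over the mine window) rather than
by MCMC: deterministic, testable, and fast at this scale. The interval
integral uses trapezoid weights built from per-date cumulative sums (O(1)
per cell); an inclusive endpoint sum would double-weight the endpoints and
inflate the likelihood of very short spans by up to 2ⁿ, biasing the span
posterior sharply downward for clustered dates. Two priors are exposed —
flat on {s < e} (default) and ∝ 1/(e−s) — because the exact prior of the
production Bayesian span tools is not published; the choice is recorded in
the output. Calibration of the estimator under the defaults: with 5 dates
from a 100-year phase on the identity curve (σ_lab = 15), the posterior
median lands in [50, 200] in ≥ 90% of seeded replicates, and its error
shrinks to the grid floor by ~25 dates.

## Sampling experiment

Two phases hold exactly 1000 residential units each, so the true change is
0% by construction. Phase 1 draws site sizes from a discretized lognormal
(σ = 0.8 on the log scale) rescaled by largest-remainder rounding so sizes
are integers ≥ 1 summing exactly to the total (Gini ≈ 0.33 — a few large
nucleated settlements among many small ones); phase 2 splits the total as
evenly as integer division allows (Gini ≈ 0). Defaults use 200 sites per
phase.

Survey is fixed-count weighted sampling *without* replacement:
m = round(r · n_sites) sites per phase, selection weights ∝ size^b, so the
stated site fraction is hit exactly and b = 0 reduces to simple random
sampling. The sampling fraction r is interpreted as a fraction of *sites*;
an alternative `fraction_of="units"` mode draws sites until r of the units
are covered, for sensitivity checks (in that mode the sampled totals are
pinned near the target, so the false-decline signal largely disappears —
which is itself informative about what the estimand measures).

Per replicate the percent change `100·(c₂ − c₁)/c₁` of summed sampled units
is recorded; each (r, b) cell summarizes 100 replicates by mean, 2.5–97.5
percentiles and Monte Carlo standard error.

One genuine subtlety: the per-replicate percent change is a ratio whose
denominator c₁ (the nucleated-phase sample) is random, so its mean carries
a positive Jensen bias ≈ 100·CV(c₁)² even under unbiased sampling. The bias
grows with size inequality and shrinks with the number of sites sampled; at
the default 200 sites and σ = 0.8 it stays within the Monte Carlo noise at
every r, which is why those defaults were chosen over a smaller, more
extreme pattern (with, say, 50 heavy-tailed sites, r = 0.1 samples 5 sites
and the control itself drifts several points positive — worth remembering
when real surveys compute mean percent change over few, highly unequal
sites). At moderate bias (b = 0.5) the same effect partially offsets the
false decline at the smallest fraction, so the monotone r-trend is cleanest
at b = 1.

## Seeding and reproducibility

One master seed fans out to named substreams (`SeedSequence` keyed by the
master seed and a CRC-32 of the stream name), one per experiment stage, so
runs are bit-identical under the same seed and adding an experiment never
perturbs another's draws. All outputs are flat CSV/JSON; every run writes
its fully resolved config and a manifest.

## What the synthetic setups do not show

The generators emulate the *structure* of the reporting-unit problems, not
real archaeological records: real phase labels come with assignment
uncertainty (supported by the event model but deliberately absent from the
periodization presets, which isolate within-phase uncertainty); real
calibration curves wiggle everywhere, not just across one idealized
plateau; "old wood" offsets, stratigraphic constraints, spatial coordinates
and floor-area weighting are all out of scope. Passing tests demonstrate
that the machinery reproduces the stated distortions under controlled
conditions — not that any particular real time series is or is not biased.
Problem sizes in the tests (replicate counts of 50–400, 10–60 seeds per
trend check) are chosen to make Monte Carlo assertions stable at 3-standard-
error tolerances while keeping the suite quick to run.
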