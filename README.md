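# repunitsim

Tactical simulations of *modifiable reporting unit problems* in count-based
time series of long-term human activity.

Archaeologists and cross-disciplinary researchers increasingly read counts of
houses, settlements, mines or radiocarbon dates per time block as proxies for
past population or activity. Those counts inherit distortions from the units
they are reported in. This package implements three seeded, configurable
simulation experiments that isolate the main distortions, together with the
chronological-uncertainty machinery they need:

1. **Periodization** (`repunitsim.popsim` + `repunitsim.timeline`) — events
   drawn from a known logistic population curve are reduced to nominal
   archaeological phase labels, then reconstructed by Monte Carlo aoristic
   analysis (each event redistributed uniformly — or by a trapezium
   distribution p(t) with corners a ≤ b ≤ c ≤ d — within its phase, binned
   into 50-year blocks, repeated 1000 times). How badly the envelope misses
   the true curve depends entirely on where the phase boundaries sit: the
   *modifiable temporal unit problem*.
2. **Duration** (`repunitsim.minesim` + `repunitsim.c14`) — exactly 100
   copper mines are in use in every year of 1750–750 BCE; only the mean
   use-life changes, declining linearly from 200 to 10 years, with
   individual durations drawn from a shifted negative binomial
   (mean μ(t), size k). The duration-blind count of distinct mines per
   century rises steeply while true activity is flat. Sampling five
   simulated ¹⁴C dates from each of 15 mines and fitting a Bayesian
   uniform-phase *span* posterior (dates θᵢ ~ U(s, e), marginal likelihood
   L(s,e) = Πᵢ [∫ₛᵉ ℓᵢ(t) dt / (e−s)] on an (s,e) grid) recovers the
   declining-duration trend — unless the dates sit on a calibration-curve
   plateau, which inflates every span.
3. **Sampling** (`repunitsim.surveysim`) — two periods with identical
   residential-unit totals (true change 0%) but different settlement-size
   structure are surveyed by sampling a fraction r of sites with detection
   weights ∝ size^b. Unbiased sampling (b = 0) recovers 0% on average;
   size-biased sampling of the nucleated period manufactures a false
   decline, stronger for smaller r and larger b.

No external data are needed: synthetic calibration curves (identity and
plateau variants) and all event tables are generated internally. Real
three-column calibration-curve files are supported via
`repunitsim.c14.read_curve`.

## Worked example

Run the sampling experiment with its defaults (two phases of 1000 units over
200 sites; nucleated phase lognormal σ = 0.8, even phase near-equal sizes;
100 replicates per cell):

```bash
$ repunitsim sampling --seed 1 --out results/sampling
  r   b       mean         lo         hi       se
0.1 0.0   2.685579 -20.000000  30.767259 1.285472
0.3 0.0   0.210299 -11.002510  11.327964 0.604973
0.7 0.0   0.351352  -4.570352   6.467988 0.291988
0.1 0.5 -12.654966 -30.069930  11.111111 1.090518
0.3 0.5 -11.995124 -20.222812  -1.639344 0.516987
0.7 0.5  -7.409482 -10.660121  -3.707088 0.195575
0.1 1.0 -24.441934 -37.136527  -7.810907 0.838621
0.3 1.0 -20.796578 -27.900284 -12.864041 0.386281
0.7 1.0 -11.857688 -13.954671  -9.548435 0.121621
```

Each row is one (r, b) cell: the mean percent change in sampled residential
units between the two periods, its 2.5–97.5% envelope and the Monte Carlo
standard error. The true change is 0%. With b = 0 every mean is within a few
standard errors of zero; with b = 1 and r = 0.1 the survey reports a ~24%
decline that never happened, and the bias shrinks as the sampled fraction
grows.

The duration experiment prints the pooled median span (years) of five dated
mines near each target founding year:

```bash
$ repunitsim duration --seed 1 --out results/duration
target_year
-1700    165.0
-1250     95.0
-800      45.0
```

True mean use-lives at those founding years are roughly 191, 105 and 20
years: the pooled spans recover the declining trend, while the naive count
written to `results/duration/naive_counts.csv` climbs from ~126 mines in the
first full century bin to ~582 in the last despite constant true occupancy.

The same functionality is available as a library:

```python
import numpy as np
from repunitsim import DurationModel, simulate_mines, in_use_counts

model = DurationModel()          # 200 yr at 1750 BCE -> 10 yr at 750 BCE
mines = simulate_mines(100, model, np.random.default_rng(0))
assert in_use_counts(mines, -1750, -750).max() == 100
```

## Configuration

Every experiment accepts a YAML config (see `repunitsim.runner`); unknown
keys are rejected, defaults are filled in, and each run writes the fully
resolved config plus a manifest next to its outputs, so a run is
reproducible from its output directory alone:

```yaml
seed: 7
duration:
  curve_kind: plateau          # put the late mines on a Hallstatt-style plateau
  plateau_calbp: [2400, 2750]
sampling:
  r_grid: [0.05, 0.2, 0.5]
```

```bash
repunitsim all --config cfg.yaml --seed 7 --out results/
```
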