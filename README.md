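# herdcycles

Mechanistic and statistical analysis of multidecadal population cycles in
large herbivores, built around caribou and reindeer (*Rangifer tarandus*).

Wild *Rangifer* herds boom and bust over decades — far longer than the
3–10-year cycles of voles, lemmings and hares — and the survey record for
any one herd rarely spans more than one or two oscillations, with many
years unsurveyed. `herdcycles` packages the two complementary ways of
studying such cycles:

* a **mechanistic arm**: a tri-trophic vegetation–herbivore–predator ODE
  model whose limit cycle can be interrogated with sensitivity sweeps over
  bottom-up (forage regrowth and standing crop) and top-down (predator
  foraging) parameters; and
* an **empirical arm**: a pipeline for gappy annual abundance series —
  Stineman interpolation of missing survey years, a bootstrap cyclicity
  test against an Ornstein–Uhlenbeck (OU) state-space null, cycle period
  and amplitude estimation, and Gaussian GLMs with backward stepwise AIC
  relating those metrics to herd-level covariates (NDVI/DHI productivity,
  winter climate, predator richness, biome, subspecies).

A synthetic-data generator reproduces the statistical anatomy of range-wide
herd compilations (series length, cycle regime, observation noise, ~40%
missing years) with a full truth table, so the entire pipeline is testable
without access to any survey compilation.

## The model

Vegetation biomass `V` (Mg km⁻²), herbivores `N` and predators `P`
(individuals km⁻²):

    dV/dt = u0 (1 − V/m) − a V N / (b + V)
    dN/dt = ξ N (a V/(b + V) − η) − c N P / (d + N)
    dP/dt = χ P (c N/(d + N) − μ) − (s0/κ) P²

Vegetation regrows linearly toward its maximum coverage `m` (herbivory
removes biomass without much plant mortality); both trophic links are
Type II functional responses; `η` and `μ` are zero-population-growth
consumption rates; the quadratic Bazykin term `(s0/κ)P²` self-limits the
predator. The herbivore conversion efficiency is derived from the intrinsic
growth rate `r0` via `ξ = r0 / (a·m/(b+m) − η)` (= 0.27 at the default
parameters). With the bundled defaults the system falls onto a limit cycle
with a **57.96-year** herbivore period and relative amplitude
`0.5 (max−min)/mean` of **0.947**.

## The cyclicity test

Sampled annually, an OU process is AR(1); the null spectrum (AR(1) plus a
white measurement-noise floor) is fitted to the periodogram by maximum
Whittle likelihood. Two statistics are computed: the standardised spectral
peak `max I_k/S_k`, and a prewhitened harmonic max-F statistic that retains
the phase coherence a periodogram discards — essential for power when the
period is comparable to the series length, as it is for these herds. Their
p-values come from a parametric bootstrap under the fitted null and are
combined with Fisher's method. Measured on OU nulls of length 60 the test
rejects at 3.8–4.3% for a nominal 5%, with ≥95% power for a 40-year cycle
of amplitude 0.9 in a 60-year window under moderate red noise.

## Worked example

```bash
# simulate the tri-trophic model and score the herbivore series
herdcycles simulate --years 3000 --burn-in 1500 --out traj.csv

# generate a synthetic 43-herd survey collection, fill the gaps,
# and test each herd for cyclicity
herdcycles synth --out-dir data --seed 7
herdcycles impute --in data/raw.csv --out data/filled.csv
herdcycles cycles --in data/filled.csv --out data/metrics.csv
# -> 13/43 herds cyclic -> data/metrics.csv

herdcycles impute-cv --in data/raw.csv --reps 20 --seed 1
# -> mean pooled correlation: 0.975 (sd 0.006, 20 reps)
```

The synthetic collection seeded 19 truly cyclic herds out of 43; with ~40%
of years missing and 10% observation noise the test certifies 11 of them,
with 2 of the 24 non-cyclic herds falsely flagged (in line with the 5%
test level) — long-period cycles in short gappy windows are intrinsically
hard to certify, which is the statistical reality this package is designed
to handle honestly. Among detected herds the mean period is 39.5 years and
the mean amplitude 0.86. In Python:

```python
from herdcycles import ModelParameters, simulate, TimeSeries, test_cyclicity

traj = simulate(ModelParameters())          # 3000 yr, 1500-yr burn-in
ts = TimeSeries(traj.times.astype(int), traj.N)
m = test_cyclicity(ts, seed=1)
print(m.period, m.amplitude)                # 57.96 0.947
```

Sensitivity sweeps (`herdcycles sweep --mode bottomup|topdown|global`)
show that in this model enriching the vegetation (higher `u0`, `m`)
shortens the herbivore cycle, while stronger predator foraging (`c`)
lengthens and amplifies it and a higher predator half-saturation (`d`)
does the reverse; see `docs/methods.md` for the full discussion, including
the one direction where the model's behaviour (amplitude growing with
enrichment — the paradox of enrichment) departs from what field intuition
about the food hypothesis might suggest.

## Layout

    src/herdcycles/
      trophic.py      ODE model, parameters, deterministic & stochastic runs
      cycles.py       periodogram, OU-null Whittle fit, cyclicity test, metrics
      sensitivity.py  bottom-up / top-down / global parameter sweeps
      imputation.py   Stineman interpolation + hold-out cross-validation
      regression.py   collinearity screen, Gaussian GLM, stepwise AIC
      synthetic.py    synthetic herd generator with truth tables
      pipeline.py     end-to-end empirical & mechanistic pipelines
      cli.py          `herdcycles` command-line interface
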