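# allostasim

A stochastic simulator of the pathway from work stress to disease, built on
allostatic load theory: neural impulses into the HPA axis drive circulating
cortisol, cortisol burdens the body reversibly (*allostatic strain*),
sustained strain above a threshold accumulates irreversible damage
(*allostatic load*), and sufficient load produces disease.  The package is
aimed at occupational-health and biobehavioural researchers who want to
simulate diurnal cortisol dynamics, study the simulated link between work
stressors and disease risk, and generate predictions for how workweek
layouts (compressed vs spread-out weeks) shape long-term health.

## The model

Each simulated person carries three fixed traits: an expected nightly
impulse count λ_N (the circadian drive behind the cortisol morning peak),
an expected work-stressor count λ_W per standard 8-hour workday, and a
cortisol decay constant ρ_C ~ N(0.52, 0.05²) per hour (implying half-lives
in the reported 60–90 min range).  Daily impulse counts are Poisson; night
impulses fall exponentially close to waking (`T_wake − Exp(1)`), work
impulses uniformly inside the work window.  Impulses are binary and last
30 minutes; simultaneous impulses add.

On the half-hour sampling grid the state equations are

    dC/dt = −ρ_C · C + κ_HPA · ΣI(t − τ)        cortisol, κ_HPA = 2.2, τ = 30 min
    dS/dt = −ρ_R · S + C                         allostatic strain, ρ_R = 0.6/h
    dL/dt = max(0, S − ε_L)                      allostatic load, ε_L = 20
    D     = (L ≥ ε_D)                            disease, ε_D = 400

integrated by forward Euler (an exact-exponential decay mode is available).
Two population scenarios are supported: night and work rates independent
(Scenario I) or coupled through an additive anticipation term,
λ_N = λ_W + Γ(1, 8) (Scenario II).  Under Scenario II the simulated
association between work-stressor exposure and disease is robust across a
27-cell grid of (ρ_R, ε_L, ε_D) values; under Scenario I it is not.

Because ρ_R, ε_L and ε_D are unscaled, absolute effect sizes and
time-to-disease values carry no real-world units; the meaningful outputs
are relative comparisons — odds ratios per SD of exposure and relative
risks between workweek configurations.

## Worked example

```python
import allostasim as al

scenario = al.ScenarioSpec("II", work_rate_dist=al.WORK_QUANTITY_UNIFORM,
                           coupling_dist=al.ANTICIPATION_COUPLING)
people = al.build_population(1000, scenario, al.DECAY_DISTRIBUTION, seed=1)
result = al.simulate_population(people, al.standard_week(), al.DynamicsParams(),
                                days=100, seed=1, keep_cortisol=True)

curve = al.day_curve(result, day_index=0)
peak = curve.loc[curve["mean"].idxmax()]
print(f"cortisol peak: {peak['mean']:.1f} at {peak.t_since_wake_hours:.1f} h after waking")
print(f"incidence by day 100: {al.incidence(result, 100):.3f}")
orr = al.odds_ratio_per_sd(result, day=100)
print(f"odds ratio per SD of work impulses: {orr.odds_ratio:.2f}")
idx = al.diurnal_indices(result)
print(f"mean AUC_G {idx.auc_g.mean():.1f}, mean wake-to-bed slope {idx.slope.mean():.2f}")
```

prints

```
cortisol peak: 26.6 at 0.5 h after waking
incidence by day 100: 0.593
odds ratio per SD of work impulses: 26.57
mean AUC_G 109.5, mean wake-to-bed slope -0.99
```

The group-mean cortisol curve peaks half an hour after waking and declines
through the day (negative wake-to-bed slope).  By day 100, 59% of this
coupled-scenario population has crossed the disease threshold, and one SD
more daily work impulses multiplies the odds of disease about 27-fold —
large because the anticipation coupling lets work demand drive the morning
peak, which dominates load accrual.

The same machinery runs from the shell:

```sh
allostasim study1 --n-people 1000 --n-days 5 --seed 1 --out results/study1
allostasim study3 --n-people 1000 --n-days 150 --seed 1 --out results/study3
allostasim simulate --config my_run.toml --seed 3 --out results/custom
```

Outputs are plain CSV tables (populations, outcomes, wake-aligned day
curves, diurnal indices, sweep odds ratios, workweek relative risks) plus a
JSON manifest.

## Layout

- `src/allostasim/population.py` — trait sampling, scenarios
- `src/allostasim/schedule.py` — workweek configurations, day resolution
- `src/allostasim/impulses.py` — impulse trains and rasterisation
- `src/allostasim/dynamics.py` — the four state equations, person and
  population simulation
- `src/allostasim/summaries.py` — day curves, AUC_G/AUC_I, slopes
- `src/allostasim/epi.py` — incidence, odds ratios, relative risks, sweep
- `src/allostasim/config.py`, `cli.py` — TOML configs and the `allostasim` CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
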