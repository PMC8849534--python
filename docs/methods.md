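# Methods

## Model

The simulator implements a minimal mechanistic chain from work stressors to
disease, following allostatic load theory.  All HPA-axis activity is
attributed to discrete neural impulses of two kinds: *night impulses*,
a circadian drive clustered just before waking that produces the cortisol
morning peak, and *work impulses*, acute stressors during working hours.
Impulses have binary intensity and a fixed 30-minute duration (matching the
approximate time course of the acute cortisol response), so the forcing at
any grid step is simply the count of impulses active at that step.

Four state variables evolve on the sampling grid:

| Variable | Equation | Interpretation |
|---|---|---|
| C (cortisol) | dC/dt = −ρ_C·C + κ_HPA·ΣI(t−τ) | delayed impulse-driven production, first-order hepatic clearance |
| S (allostatic strain) | dS/dt = −ρ_R·S + C | reversible physiological burden, proportional recovery |
| L (allostatic load) | dL/dt = max(0, S − ε_L) | irreversible damage from strain above the allostatic threshold |
| D (disease) | D = (L ≥ ε_D) | absorbing disease state |

Only the "too-frequent allostasis" route to load is modelled; prolonged or
inadequately regulated allostasis, hypocortisolism and health-behaviour
routes are deliberately outside the model.  Strain and load are unscaled
quantities, so absolute incidences and times-to-disease are not meaningful;
all substantive outputs are *relative* (odds ratios per SD of exposure,
relative risks between schedules).

## Parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| ρ_C | per person, N(0.52, 0.05²) | 1/h | implies half-lives 60·ln2/ρ_C ≈ 70–92 min across ±2 SD, matching the reported 60–90 min inter-individual range |
| κ_HPA | 2.20 | concentration per active impulse per hour | calibrated so simulated day curves sit on the reported salivary-cortisol scale (treated as arbitrary units on the nmol/L scale) |
| τ | 0.5 h | h | cortisol lags its neural trigger by about 30 min |
| ρ_R | 0.6 | 1/h | recovery coefficient of strain; unscaled, swept in robustness analyses |
| ε_L | 20 | strain units | allostatic threshold; unscaled, swept |
| ε_D | 400 | load units | disease threshold; unscaled, swept |
| λ_N | per person, Γ(3, 14) | impulses/night | mean 42 nightly impulses reproduces a realistic morning peak |
| λ_W | per person, Γ(3, 6) or U(1, 50) | impulses per 8-h workday | gamma marginal for realistic populations; the uniform variant spreads exposure evenly to sharpen dose-response estimation |
| coupling | Γ(1, 8) | impulses/night | additive anticipation term linking night to work rates (Scenario II) |
| wake / work start | 07:00 / 08:30 | clock | standard daily template |
| sampling | 2 per hour (dt = 0.5 h) | — | equals the impulse duration, so one impulse occupies one grid step |

Scenario I draws λ_N and λ_W independently; Scenario II sets
λ_N = λ_W + Γ(1, 8).  The coupled construction preserves the work-rate
marginal while inducing corr(λ_W, λ_N) = √(Var λ_W / (Var λ_W + 64)) ≈ 0.79
for the gamma work marginal.  Note its night-rate mean (≈ 26 with Γ(3,6)
work rates) is lower than Scenario I's 42; the coupling distribution is
exposed in configuration for recalibration.

### Anticipation and day length

The morning peak is read as (partly) anticipatory: the night before a more
demanding day produces a larger peak.  Two consequences:

1. Work-impulse expectations scale linearly with the working day:
   an h-hour day carries λ_W·h/8 expected stressors.
2. For coupled populations, the work-rate component of the night rate
   follows the *actual* daily demand: λ_N(h) = λ_N + λ_W·(h − 8)/8
   (the `anticipation_scaling` flag; identity at the 8-hour reference day).

The second point is a substantive modelling choice.  With the night rate
frozen at its 8-hour reference value, workweek layouts with equal weekly
hours are nearly indistinguishable in outcome — load accrual is dominated
by the morning peak, which would then be layout-independent — and the small
residual effect actually *favours* compressed weeks, because on spread-out
layouts work impulses ride the post-peak strain tail on more mornings.
Scaling the anticipated demand with day length is what produces the
compressed-week risk excess and the spread-week protection, and is the
reading consistent with treating the peak as anticipation of the upcoming
day.  Workweek comparisons enable it by default; it can be disabled to
study the frozen-rate variant.

## Numerical choices

- **Integration.**  Forward Euler with dt = 0.5 h; the per-step cortisol
  decay factor is 1 − ρ_C·dt = 0.74, vs e^(−ρ_C·dt) ≈ 0.771 for the exact
  update, so Euler shortens the effective half-life slightly.  An
  `exact` decay mode is provided; all qualitative results hold under
  either.  Steps with ρ·dt ≥ 1 are rejected as unstable.
- **Initial conditions and pre-roll.**  C = S = L = 0 at midnight of day 0
  (a Monday).  Night impulses whose exponential offset reaches behind
  midnight land on a 24-h pre-roll segment that forces cortisol only; the
  pre-roll never appears in outputs.
- **Rate reading of the load equation.**  The load increment is
  dt·max(0, S − ε_L); without the dt factor the load scale would depend on
  the sampling rate, contradicting the continuous-time statement.  Since
  ε_L and ε_D are arbitrary, only relative results could be affected, and
  they are not.
- **Boundary conventions.**  Strain exactly at ε_L contributes nothing
  (strict excess); load exactly at ε_D is diseased (inclusive threshold).
- **Impulse rasterisation.**  An impulse occupies exactly the grid step
  containing its onset; simultaneous impulses add.  The total gridded count
  equals the number of in-horizon impulses (conservation).
- **Seeding.**  A master seed spawns one substream per person (prefix-
  stable: enlarging the population never perturbs earlier people), split
  into separate night and work streams.  Workweek comparisons therefore
  share identical night-impulse realisations across configurations
  (common random numbers), which sharply reduces the Monte-Carlo variance
  of relative risks.
- **Odds ratios.**  Logistic fit (statsmodels) of disease-by-day on the
  z-scored realised mean daily work-impulse count.  Perfect separation and
  estimates above 100 are reported as the cap value 100; outcomes without
  variation yield an explicitly flagged undefined (NaN) ratio, never a
  silent drop.  The latent rate λ_W can be substituted for the realised
  exposure by a switch.
- **Overnight work windows.**  The work window opens at a fixed clock time,
  so the most compressed long-hour layouts (e.g. 3 × 16h40m) run past
  midnight.  These windows are allowed (with a logged warning) rather than
  rejected, since the layout grid explicitly includes them; only daily
  durations above 24 h are errors.

## Open design choices

- **Bedtime** is undefined in saliva-protocol terms; the wake-to-bed slope
  fixes bed at wake + 16 h and uses the two-endpoint difference (a
  regression mode over all samples is available).
- **Diurnal indices** are computed on the full half-hour simulation grid
  rather than sparse saliva sampling points; the day window is
  configurable.
- **Robustness sweep grid**: the three values per parameter bracket the
  reference values geometrically — ρ_R ∈ {0.3, 0.6, 1.2},
  ε_L ∈ {10, 20, 40}, ε_D ∈ {200, 400, 800} — package defaults,
  overridable in configuration.
- **Checkpoint days** default to {50, 100, 150, 200}.
- Per-person rates are constant across days (no weekday/weekend modulation
  of the night rate, no day-to-day carry-over), and ρ_R, ε_L, ε_D are
  shared by all persons.

## What the generator does and does not emulate

The synthetic populations reproduce: heterogeneous decay constants and
impulse rates, the characteristic group-level day curve (steep pre-waking
rise, peak ≈ 30 min post-wake, gradual daytime decline), negative
wake-to-bed slopes, and a disease mix in which some people never accrue
load.  They do not emulate: stressor-duration variability, perseverative
prolongation of stressors, evening/non-work stressors (simulated cortisol
reaches zero at night, unlike field data), measurement noise of sampled
cortisol, or inter-individual variation in recovery and thresholds.
Conclusions from simulated populations therefore speak to the model's
internal logic, not directly to field populations.

## Behaviour worth knowing

- Load accrual is concentrated around the morning peak rather than spread
  across the workday: under reference settings roughly three quarters of
  all load accrues within four hours of waking (hourly shares ≈ 30%, 29%
  and 16% for the first three post-wake hours vs ≈ 2%/h in the afternoon).
  It is *not* concentrated within the first two hours: strain follows
  cortisol with time constant 1/ρ_R ≈ 1.7 h, so the above-threshold excess
  peaks ≈ 2–2.5 h after waking (analytically, ln(ρ_R/ρ_C)/(ρ_R − ρ_C)
  ≈ 1.8 h after the cortisol peak).
- Under the coupled scenario the odds ratio per SD of work exposure
  exceeds 1 for every parameter combination in the default sweep with a
  defined estimate; under the uncorrelated scenario the association is
  weak or absent for part of the grid — acute work impulses alone
  contribute comparatively little load.
- Workweek comparisons at matched weekly hours order by hours-per-day:
  compressed layouts raise risk, spread-out layouts lower it, and moving a
  free day mid-week at constant day length changes essentially nothing.

## Problem sizes

Simulation studies in the test suite run at reduced scale chosen for
statistical adequacy: 2,000 people × 5 days for day-curve shape, 500
people × 100 days for the 27-cell robustness sweep (both scenarios), 1,000
people × 150 days for the workweek ordering, and 20,000 observations for
odds-ratio calibration.  Library defaults reproduce the full-scale setups
(10,000 or 5,000 people × 200 days).
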