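# Methods

## Data model and conventions

One observation row per individual per day alive. Age is 0-based: age 0 is
the day the egg was laid, `death_age` is the last day the individual was
seen alive, lifespan = death_age + 1. Stage order is egg < larva < pupa <
adult, with exactly one adult stage (female or male) per individual; sex is
`undetermined` only for pre-adult deaths (sex is determined at pupation in
the rearing design). A missing daily row is an error, never imputed.

Trait conventions:

- Stage durations average over individuals that **completed** the stage;
  an individual dying mid-stage is excluded from that duration mean but
  still contributes to survival everywhere.
- APOP = first-oviposition age − adult-emergence age. TPOP =
  first-oviposition age + 1 (days since the egg was laid, counting the
  laying day), chosen so that TPOP = pre-adult duration + APOP holds exactly
  individual by individual; the convention is recorded in output metadata.
- Oviposition days and APOP/TPOP average over females that actually laid;
  fecundity averages over **all** adult females, including zero-layers.
- SEs are sample SEs (sd/√n, ddof = 1), undefined (NaN) below n = 2.

## Life-table core

`s_xj = n_xj / n` with the initial egg number as the fixed denominator.
`m_x` is total eggs at age x over total alive at age x (0, never NaN, when
nobody or no female is alive). `R0 = Σ l_x m_x` equals total eggs / n
exactly, which yields the machine-precision identity
`R0 = (females/n) × mean fecundity per female` used as a test oracle.

The intrinsic rate solves `Σ_x exp(−r(x+1)) l_x m_x = 1`. The `x+1`
exponent is the standard convention of the two-sex framework for 0-based
ages — eggs laid during day x enter the census as newborns on day x+1 —
and is fixed; changing it shifts r materially. The root is found by
deterministic bracketing bisection starting from [−1, 2] d⁻¹ with outward
doubling, ~200 bisection steps (machine precision), and a final residual
check at tolerance 1e−12. The residual is evaluated only over ages with
positive maternity so that the bracket search stays finite-or-infinite
(never NaN) under exp overflow. `T = ln(R0)/r`; in the r → 0 limit it falls
back to the cohort generation time `Σ (x+1) l_x m_x / R0`.

Daily transition probabilities per (age, stage) — stay, advance (pupa
splits into female/male), die — are pooled empirical fractions with no
smoothing, which keeps the model faithful to the observed cohort: forward
propagation of these fractions from (0, egg) reproduces `s_xj` exactly.
Life expectancy and reproductive value are backward recursions

    e_xj = 1 + Σ_k P[x,j,k] e_{x+1,k}
    v_xj = f_xj + e^{−r} Σ_k P[x,j,k] v_{x+1,k}

so `e_xj` counts the current day (e = 1 at a lineage's terminal age) and
`e_01` equals the cohort mean lifespan exactly; `Σ_j s_0j v_0j = λ`. Both
recursions are verified in the tests against independent explicit forward
summation of the propagated survival matrix.

Degenerate inputs: a cohort that never reproduces has R0 = 0; r, λ, T and
v_xj are then undefined, and the fit either raises ("no reproduction,
r undefined") or, on request, returns NaN parameters so that projection of
pure attrition and bootstrap replicates without reproduction remain
well-defined.

## Bootstrap

The resampling unit is the whole individual life history (individuals are
the independent units of the rearing design). Each replicate is a
multinomial multiplicity vector over individuals, so schedules and trait
means are matrix products and the renewal equation is solved for all B
replicates simultaneously by vectorised bisection. Replicates whose
resample contains no reproducing female have undefined r, λ and T: they are
stored as NaN, excluded from the bootstrap mean/SE and counted in
`n_undefined` (R0 = 0 is retained). The full-length replicate vector (with
NaN markers) is kept so that paired tests can match replicate i to
replicate i.

Paired bootstrap tests use the percentile CI of the matched replicate
differences; significance ⇔ the CI excludes 0. The CI type is percentile
(the simplest reading of "confidence interval of the difference"); no BCa
or studentisation, and no multiple-testing correction across the all-pairs
letter display — both stated in output metadata. Letters follow the
standard compact-letter-display insert-and-absorb algorithm in descending
order of bootstrap means. Per-treatment streams are independent, seeded
from the master seed by fixed prime offsets (seed + 7919·i mod 2³¹). The
default B is 1,000 for interactive/CI use; the study-scale 100,000 is a
config value, not a constant.

## Projection

Expected-value renewal process: a cohort of E eggs with age-0 day b
contributes `E·s_{t−b,j}` to stage j on day t and lays `E·lm_{t−b}` eggs
during day t; those eggs form the age-0 cohort of day **t+1**. The next-day
census is the timing consistent with the `x+1` renewal exponent, and it is
what makes the projection's asymptotic daily growth factor converge to
λ = e^r of the same schedule (verified to 1e−3 in the acceptance suite; the
laying-day alternative converges to a different, larger root). Counts are
real-valued expectations, exactly linear in the initial egg number; stage
membership uses `s_xj` directly with no re-normalisation. The asymptotic
growth factor is the geometric mean of daily ratios over a trailing window;
stabilisation is the earliest day after which the stage-proportion vector
moves less than a tolerance (default 1e−4, max-norm) between all subsequent
consecutive days.

## Synthetic cohorts

The generator emulates the constant-temperature design: ~150 eggs per
treatment (50 × 3 replicates collapsed into one cohort), daily census,
~1:1 sex ratio. Per individual: independent discretized truncated-normal
stage durations (whole days, min 1); per-stage completion probabilities
with in-stage death on a uniform day; per-sex discretized-normal adult
longevity; and for females an APOP, an oviposition-window length and a
discretized-gamma total fecundity, the total spread multinomially over the
window under a gamma-shaped (default, early-peaked) or uniform daily
envelope.

Design choices where the published material is silent:

- **Dispersion.** The published tables print SEs of means, not individual
  SDs; preset SDs are SE·√n with effective n = 120 for immature-stage
  traits and n = 30 for adult/reproductive traits, floored at 0.5 d. This
  is calibration to a plausible study design, not an inference about the
  real cohorts. The resulting broad larval-duration spread matches the
  wide reproductive spans visible in the published age schedules.
- **Survival.** Overall pre-adult survival is set so that the config's
  closed-form R0 (= sex ratio × survival × mean fecundity) reproduces the
  reported R0 scale at each temperature; the egg-stage share follows the
  reported qualitative ordering (highest at 27 °C). Only orderings, not
  curve values, are asserted anywhere.
- **Longevity/oviposition coupling.** A female's adult lifespan is extended
  to max(longevity draw, APOP + window) so she always completes her
  oviposition schedule. This keeps realized mean fecundity exactly at the
  configured target and the analytic schedule closed-form, at the cost of
  slightly inflating female longevity relative to its nominal mean when the
  longevity draw is short.

Because every ingredient has finite support, the exact expected schedules
(l_x, m_x, per-stage occupancies) are computable by convolution with no
sampling; `analytic_params` runs the same renewal solver on those exact
schedules and provides the ground truth for parameter recovery. The six
presets' analytic r reproduce the published qualitative thermal response
(maximum at the 27 °C preset, minimum at 36 °C).

What the generator does **not** emulate: between-replicate (petri-dish)
heterogeneity, observed APOP/oviposition-day counts as sampled quantities
(days with zero multinomial eggs lengthen observed APOP and shorten
observed oviposition days relative to the configured values), correlations
between development speed and fecundity, and the exact published survival
curves or Table-2 values — the raw cohorts are unpublished, so presets are
structurally, not numerically, faithful. A green recovery test therefore
establishes that the estimator recovers the generator's own truth, not that
the generator reproduces the original insects.

## Numerical notes

- Stage columns are fixed: egg(1), larva(2), pupa(3), female(4), male(5);
  fecundity is defined only for the female column.
- Sums are truncated at the last observed age (l_x = 0 beyond it).
- Identical (cohort, B, seed) give bit-identical bootstrap output; the CLI
  writes fixed 6-decimal TSVs so whole pipeline reruns are byte-identical.
- Clone cohorts give bootstrap SEs that are zero up to float accumulation
  in `np.std` (≤ 1e−12 relative).

## Known limitations

- Daily resolution only; no continuous-age or interpolated life tables, no
  degree-day/thermal-threshold regression.
- Percentile CIs can be slightly anti-conservative at small n; the type-I
  error of the paired test is verified at ~5 % for n = 150.
- The compact letter display reports unadjusted pairwise tests, as in the
  source tables.
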