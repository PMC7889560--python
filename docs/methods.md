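# Methods

## Model and assumptions

`surrofrax` computes 10-year probabilities of hip fracture and of
major osteoporotic fracture (MOF) as **cause-specific cumulative
incidences of a first fracture**, with death as a competing exit from
the fracture-free state. This is the standard output definition of
fracture-risk calculators: a person who dies fracture-free inside the
horizon contributes no fracture, so raising mortality always lowers
the fracture probability. It is *not* an ever-fractured prevalence and
not `1 − exp(−Λ_f)`, which ignores the competing risk.

Both hazards are **step-constant within age bands** (default 5-year
bands 50–54 … 85–89 plus an open 90+ band, half-open `[lo, hi+1)` in
integer years, matching WHO/UN table conventions). No within-band
interpolation or smoothing is applied; ages beyond the last closed
band use the open band's rate for the remainder of the horizon. Under
step-constant hazards the cumulative-incidence integral is exact:
per segment of length Δ with constant fracture hazard h_f, death
hazard h_d and fracture-free survival S on entry,

    P += S · h_f/(h_f+h_d) · (1 − e^{−(h_f+h_d)Δ}),   S ← S·e^{−(h_f+h_d)Δ},

with segments split at every band boundary of either hazard and at
the horizon end. The implementation uses `expm1`, so the horizon → 0
limit is linear in Δ to ~1e-10 relative precision and re-splitting
segments changes nothing to machine precision.

The individual fracture hazard is a multiplicative layer on the
population baseline incidence: a hazard ratio per active binary
clinical risk factor (CRF), a gradient-of-risk term
`g^(T_ref − T)` in the femoral-neck T-score, and a calibration
divisor. The surrogate construction itself replaces only the
mortality tables: the surrogate inherits the reference model's hip
and MOF incidence and its risk-coefficient layer unchanged.

## Parameters that matter

| parameter | units / default | notes |
|---|---|---|
| age banding | 5-year bands, floor 50, open 90+ | configurable floor and width |
| horizon | 10 years | the standard reporting horizon |
| CRF fracture hazard ratios | synthetic defaults 1.3–1.9 | authentic coefficients are proprietary; config-file replaceable |
| CRF death hazard ratios | 1 (off) | supported per-CRF; magnitudes not public, so off by default |
| gradient of risk | 1.6 per SD T-score decrease | T_ref = 0 |
| calibration divisor | 1 (no re-calibration) | maps population-average rates to reference-profile rates when the constant is known |
| BMI | profile attribute, 26 kg/m² in the protocol | no BMI→risk function is active by default |
| comparison grid | 2⁶ CRF states × 8 T-scores (0 … −3.5 by 0.5) | 512 profiles per (age, sex); ages 50, 60, 70, 80 |
| regression knot | 35% on the reference-probability axis | continuity enforced at the knot |
| tolerance-interval window | 101 profiles, 95% coverage | see below |

Rates are stored per 100,000 person-years on disk (epidemiological
reporting convention) and per person-year in memory. MOF:hip
multipliers must be ≥ 1 band-wise because hip fractures are a subset
of MOF, which also forces p_hip ≤ p_mof for every profile.

## Comparison protocol decisions

The tolerance-interval construction around the reference-model median
is genuinely open in the protocol descriptions this follows. The
package uses a **nonparametric rank-window TI**: sort the 512 pairs by
the reference probability, take the 101 profiles whose reference ranks
are nearest the median, and report the reference median plus the
empirical 2.5th/97.5th percentiles of the paired
(comparison − reference) differences in that window. Anchoring on
paired differences makes the interval describe *model disagreement*
for individual cases near the median — identical models, or models
offset by a constant, give a zero-width interval — rather than the
spread of absolute risk across neighbouring profiles. A
regression-residual variant was considered and rejected as less
distribution-free. The median for the even grid size 512 is the mean
of the 256th and 257th order statistics; grid profiles are equally
weighted (no population prevalence weighting). Grid row order is
deterministic (T-score outermost, CRFs as a binary counter) so outputs
are byte-stable.

When no point lies above the 35% knot the above-knot slope-change
coefficient is fixed at 0 and flagged rather than estimated from an
all-zero design column.

## Projection conventions

Expected counts are rate × exposure sums, treating mid-year population
as person-years at risk, with incidence held fixed over calendar time.
Counts are reported rounded to the nearest integer but totals and
percent increases are computed from the **unrounded** values; percent
increases round half-up to integers for reporting (with exact rational
arithmetic when both counts are integers, so a true .5 never rounds
down through float noise). Re-dividing already-rounded counts can
differ from the reported increase by a point, which is why the
unrounded chain is kept.

## What the synthetic generator emulates — and what it does not

The real inputs of a surrogate build (reference-country hip-fracture
incidence, index-country life table, registry MOF:hip ratios, UN
population projections, the proprietary risk coefficients) are not
redistributable, so the generator produces stand-ins with the
structural features the method assumes:

- **Gompertz hazards** `α·e^{β·(midpoint − floor)}` for mortality and
  hip incidence — the simplest form matching the near-universal
  log-linear age pattern. Defaults: male mortality α=0.008, female
  α=0.006, β=0.075 (≈0.8%/yr at the early 50s to ≈19%/yr at 90+); hip
  incidence α=0.00015, β=0.105 (≈20 to ≈1,300 per 100,000/yr), female
  excess 1.5× above age 60.
- **Age-declining MOF:hip ratios** from ≈6 at the floor toward an
  asymptote of 1.5, female ≥ male — younger people break wrists and
  humeri far more often than hips.
- **A young, growing pyramid** (20 million aged 50+, 2%/yr geometric
  growth) whose band-decay rate shrinks over calendar time, shifting
  mass into older bands (demographic ageing).
- **A demo pair** whose index mortality is the reference mortality
  scaled from ≈1.05× at the floor to 2× at the oldest bands, emulating
  a markedly higher-mortality index country.

Everything is closed-form and deterministic, so fixture files are
byte-identical across runs. What passing tests on these fixtures show
is that the *machinery* is correct — the integration exact, the
monotonicities and identities guaranteed, the qualitative surrogate
signature (near-equal medians at 50, lower at 70–80, correlations
near 1) reproduced. They do **not** validate any real country's
absolute probabilities: cohort effects, non-Gompertz old-age mortality
plateaus, secular incidence trends, urban/rural and ethnic incidence
variation, and the authentic risk-coefficient values are all outside
the generator.

## Numerical choices and degenerate inputs

- Band lookup is right-continuous: age exactly at a boundary belongs
  to the upper band; ages below the floor are a domain error.
- `expm1` in the integrator avoids cancellation for tiny segments.
- Self-correlation short-circuits to exactly 1.0 for bit-identical
  columns; constant columns are an error, not NaN.
- Degenerate regression designs (all reference probabilities equal)
  raise rather than returning arbitrary coefficients.
- A tolerance-interval window below 20 warns (percentile estimates
  unstable at that size).
- Problem sizes in the verification suite — 10⁶ Monte-Carlo draws ×
  27 hazard/horizon triples, the full 512-profile grid at 4 ages × 2
  sexes, 100 regression replicates — were chosen to make the checks
  sharp (3 Monte-Carlo SE, slope bias < 0.05) while keeping the whole
  suite around a quarter minute.

## Known limitations

- The shipped risk coefficients are synthetic; absolute probabilities
  from the default config are demonstrations, not clinical estimates.
- One-year probabilities, T-score computation from raw BMD, secular
  incidence trends and uncertainty intervals on projections are out of
  scope.
- The MOF:hip ratio transport assumption (same age/sex ratio in the
  target population as in the source registry) is inherited from the
  field's practice and cannot be tested from within the package.
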