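# surrofrax

Surrogate country-specific 10-year fracture-probability models.

Many countries have no usable hip-fracture epidemiology, so a
country-specific fracture-risk calculator cannot be built from local
data. The established workaround is a **surrogate model**: take
age- and sex-specific hip-fracture incidence from a reference country
whose rates are judged representative, impute the incidence of the
remaining major osteoporotic fractures (MOF: hip, clinical spine,
distal forearm, proximal humerus) from registry MOF:hip ratios, and
pair that fracture incidence with the **index country's own
mortality**. `surrofrax` implements that construction end to end for
epidemiologists and bone-health researchers:

- typed CSV I/O for age-band × sex rate, ratio and population tables
  (`rates_io`),
- the surrogate builder and MOF imputation (`surrogate`),
- a competing-risk probability engine (`prob_engine`),
- the model-comparison protocol over a factorial clinical-risk-factor
  (CRF) / BMD grid (`compare`),
- national hip-fracture burden projection (`projection`),
- a synthetic-data generator so everything runs offline
  (`synthetic_data`),
- a `surrofrax` command-line interface over all of it.

## The model

For an individual of age *a* the annual fracture hazard is the
population baseline incidence modified by a multiplicative risk layer

```
h_f(t) = λ(t) · Π_j HR_j^{x_j} · g^{(T_ref − T)} / c
```

where λ(t) is the band-constant baseline incidence at age *t*, x_j are
the six binary clinical risk factors (prior fracture, parental hip
fracture, current smoking, glucocorticoids, rheumatoid arthritis,
alcohol ≥ 3 units/day) with hazard ratios HR_j, *g* is the gradient of
risk per SD decrease of femoral-neck T-score *T*, and *c* a
calibration divisor. The 10-year probability is the cause-specific
cumulative incidence of a *first* fracture with death as a competing
risk. Both hazards are step-constant over the age bands, so the
integral is exact: on each segment of length Δ with constant hazards
h_f, h_d and entry survival S,

```
P += S · h_f/(h_f+h_d) · (1 − e^{−(h_f+h_d)Δ}),    S ← S · e^{−(h_f+h_d)Δ}.
```

Two models are compared on the standard factorial array — every CRF
combination × T-scores 0 to −3.5 SD in 0.5 SD steps at BMI 26 kg/m²,
2⁶ × 8 = 512 profiles per (age, sex) — via Pearson correlation,
piecewise linear regression with a fixed knot at 35% probability,
and medians with 95% nonparametric tolerance intervals. Burden
projections multiply age/sex incidence by population pyramids per
calendar year with incidence held fixed.

The authentic FRAX beta coefficients are proprietary; the shipped
risk-coefficient config is clearly-labelled **synthetic** and fully
replaceable (`risk_coefficients.cfg`, flat `key = value` format).

## Worked example

```python
import surrofrax as sx

# synthetic reference model + a higher index-country mortality
reference, index_mortality = sx.make_demo_pair(sx.SyntheticSpec())
surrogate = sx.build_surrogate(reference, index_mortality, "index-country")

# one patient
profile = sx.RiskProfile(age=70, sex="female", bmi=26,
                         crf={"prior_fracture"}, tscore=-2.5)
res = sx.compute_probabilities(surrogate, profile)
print(f"p_mof: {100 * res.p_mof:.1f}%   p_hip: {100 * res.p_hip:.1f}%")

# full 512-profile grid comparison at ages 50..80
cmp = sx.run_comparison(reference, surrogate)
print(cmp.summary[["age", "sex", "outcome", "r", "median_a", "median_b"]]
      .query("sex == 'male' and outcome == 'mof'").round(3))
```

prints

```
p_mof: 32.9%   p_hip: 12.9%
     age   sex outcome      r  median_a  median_b
0   50.0  male     mof  1.000    10.254    10.168
4   60.0  male     mof  1.000    18.867    18.061
8   70.0  male     mof  1.000    32.408    28.413
12  80.0  male     mof  0.996    46.980    35.520
```

The correlations stay near 1 — the surrogate preserves the *ranking*
of risk — while the medians fall increasingly below the reference at
older ages, the expected signature of pairing the same fracture rates
with a higher competing mortality. The same operations are available
from the shell; `surrofrax --help` lists `validate-tables`,
`build-surrogate`, `prob`, `compare`, `project` and `synth`.

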