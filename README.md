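# ctdose

Bayesian analysis of contrast-enhancement attainment and contrast-medium
dosing for hepatic dynamic CT protocols.

## The problem

Detecting hypervascular liver tumours on dynamic contrast-enhanced CT
requires sufficient enhancement: by convention > 280 HU in the abdominal
aorta during the hepatic arterial phase (HAP) and > 50 HU in the hepatic
parenchyma during the portal venous phase (PVP). With a fixed
weight-adjusted injection (2.0 mL/kg of a 300 mgI/mL agent, i.e.
600 mgI/kg), enhancement varies widely between patients, and it varies
with tube voltage: at 100 kVp the iodine signal is stronger than at
120 kVp because the beam energy lies closer to the iodine K-edge.

The clinically useful question is not the *mean* enhancement of a
protocol but the *probability* that a given patient attains the
diagnostic threshold — a quantity frequentist summaries do not deliver
directly, and the natural target of a Bayesian analysis. `ctdose`
implements that analysis as a tested, reusable pipeline for two-arm
(100 vs 120 kVp) protocol comparisons, together with a seeded synthetic
cohort generator so every stage is runnable without patient data.

## The model

Each patient's observed enhancement E (ΔHU, post-contrast minus
unenhanced) is converted to the **required volume**: the contrast dose
per kg that would have brought that patient exactly to the threshold T,
under dose–enhancement proportionality at fixed injection duration:

    v = v_admin · T / E          (mL/kg, v_admin = 2.0 mL/kg)

Required volumes are modelled as i.i.d. normal(μ, σ²) with a uniform
(flat) prior on (μ, σ) inside wide bounds. The posterior is sampled by
a conjugate two-block Gibbs sampler (five chains × 21,000 draws,
burn-in 1,000 → 100,000 retained draws), and has closed-form marginals
used as an exact oracle in the test suite:

    μ  | y  ~  ȳ + s·√((n−1)/(n−2))/√n · t(n−2)
    σ² | y  ~  (n−1)·s² / χ²(n−2)

Two per-draw derived quantities summarise each protocol arm:

* **attainment probability**  p = Φ((v_admin − μ)/σ): the fraction of
  patients whose required volume does not exceed the administered dose —
  equivalently, the probability of diagnostic enhancement;
* **coverage dose**  q = μ + z(0.95)·σ: the dose at which 95% of
  patients attain diagnostic enhancement (z(0.95) ≈ 1.6449).

Both are reported as posterior mean ± SD with 95% credible intervals,
split-chain Gelman–Rubin R-hat and effective sample sizes.

## Worked example

Reproduce the default two-arm study (moment-matched synthetic cohorts
of n = 100 per arm at the published enhancement moments):

```bash
ctdose reproduce --seed 0 --out out/
```

which prints (and writes to `out/report.md` / `out/report.json`):

```
| Protocol | Site | Enhancement (HU) | Attainment | Required volume (mL/kg) | P(optimal enhancement) | 95% coverage dose (mL/kg) |
|---|---|---|---|---|---|---|
| 100 kVp | aorta | 395.9 ± 65.1 | 94/100 | 1.455 ± 0.258 | 98.2 ± 0.8 % | 1.879 ± 0.040 |
| 100 kVp | liver | 73.9 ± 15.5 | 93/100 | 1.422 ± 0.350 | 95.0 ± 1.6 % | 1.998 ± 0.054 |
| 120 kVp | aorta | 340.9 ± 51.4 | 90/100 | 1.681 ± 0.265 | 88.5 ± 2.6 % | 2.117 ± 0.041 |
| 120 kVp | liver | 57.8 ± 11.8 | 76/100 | 1.806 ± 0.398 | 68.7 ± 3.7 % | 2.461 ± 0.062 |
```

Reading the 120 kVp aorta row: the cohort's arterial-phase enhancement
averaged 340.9 ± 51.4 HU; 90 of 100 synthetic patients exceeded 280 HU;
the posterior mean required volume is 1.681 ± 0.265 mL/kg, so a
2.0 mL/kg injection achieves diagnostic aortic enhancement with
posterior probability 88.5 ± 2.6%, and 2.117 ± 0.041 mL/kg would be
needed to cover 95% of patients. At 100 kVp the same dose covers 98.2%
of patients for the aorta and 95.0% for the parenchyma — the
quantitative case for the lower-voltage protocol. The cross-arm t tests
confirm the enhancement difference between voltages (p < 0.01).

The same analysis is available programmatically:

```python
from ctdose import default_study_config, run_study, render_report

report = run_study(default_study_config(seed=0))
print(render_report(report, "markdown"))
```

and on your own per-patient CSV cohorts via `ctdose analyze
--cohort a.csv --cohort b.csv --out out/` (header documented in
`ctdose.cohort.COHORT_COLUMNS`).

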