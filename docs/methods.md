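# Methods

## Scope and data flow

`ctdose` analyses two-arm hepatic dynamic CT protocol studies. The
pipeline is generate (or load) → measure → transform → infer → report:

1. **Cohort** (`ctdose.cohort`): synthetic per-patient CT numbers for
   one protocol arm, or a user-supplied cohort CSV.
2. **Enhancement** (`ctdose.enhancement`): ΔHU per patient and site,
   empirical attainment counts, cross-arm t and chi-square tests.
3. **Dose transform** (`ctdose.dose`): per-patient required contrast
   volume (mL/kg) to just reach the diagnostic threshold.
4. **Inference** (`ctdose.bayes`): flat-prior normal-model MCMC with a
   closed-form oracle, attainment probability and coverage dose.
5. **Report** (`ctdose.pipeline`): one cell per arm × site, JSON and
   markdown renderings, provenance (seed, config hash, version).

DICOM handling, ROI measurement, bolus timing, radiation-dose (DLP)
analysis and renal-function screening are out of scope; the pipeline
starts from tabular CT numbers.

## Enhancement and attainment

Enhancement is the post-contrast minus unenhanced CT number at the same
site: the aorta uses the hepatic arterial phase, the hepatic parenchyma
the portal venous phase with the right and left lobes averaged at equal
weights before subtraction (for equal weights, averaging before or
after subtraction is identical). Attainment is strict: a value exactly
at the threshold (280 HU aorta, 50 HU parenchyma) does not count.
Non-positive enhancements are flagged, kept in descriptive statistics,
and excluded (with a logged count) only from the dose transformation.

The cross-arm comparisons use the pooled-variance Student t test
(Welch available by flag) and the Pearson chi-square test without
continuity correction — at ~100 patients per arm the Yates correction
is immaterial; a flag enables it.

## Required-volume transformation

At fixed injection duration and iodine concentration, enhancement is
taken proportional to the iodine dose per kg — the standard
contrast-media kinetics assumption. Hence the volume a patient needed
to just reach threshold T after receiving v_admin is
v = v_admin·T/E, with the exact identity v·E = v_admin·T. This linear
reconstruction is the unique simple form consistent with the posterior
summaries it must reproduce: for the 120 kVp aorta,
2.0×280/E at E ~ (340.9, 51.4) gives a mean volume of ~1.68 mL/kg, and
Φ((2.0−1.681)/0.264) = 88.7% and 1.681+1.6449·0.264 = 2.115 mL/kg
reproduce the published probability and coverage dose; likewise for the
other three arm × site combinations.

Because 1/E diverges as E → 0, enhancements at or below a positivity
floor (T/10 by default) are excluded; each exclusion carries the
patient id. The floor is arbitrary but inert under realistic inputs:
at the study's moments the smallest enhancement is > 4 SDs above it.

## The Bayesian model

Required volumes are i.i.d. normal(μ, σ²) with a uniform prior on
(μ, σ) inside finite bounds — defaults μ ∈ [0, 10] mL/kg,
σ ∈ (10⁻⁶, 5] mL/kg (μ ∈ [0, 1000] HU, σ ∈ (10⁻⁶, 500] HU for fits in
enhancement space). The bounds are wide enough to be effectively flat:
widening them tenfold changes summaries by < 0.1% at n = 100 (tested).
The prior is uniform on σ, not log σ; the oracle formulas below match
that choice (n−2 degrees of freedom rather than Jeffreys' n−1 — the
difference is negligible at n = 100, but oracle and sampler must agree
exactly).

With S(μ) = Σ(yᵢ−μ)², the posterior is p(μ,σ|y) ∝ σ⁻ⁿ exp(−S(μ)/2σ²)
on the prior box, with closed-form marginals

* μ | y = ȳ + s·√((n−1)/(n−2))/√n · t(n−2), hence
  SD(μ|y) = (s/√n)·√((n−1)/(n−4));
* σ² | y = (n−1)s²/χ²(n−2), hence E[σ²|y] = (n−1)s²/(n−4) and
  E[σ|y] = √((n−1)s²/2)·Γ((n−3)/2)/Γ((n−2)/2).

These need n ≥ 4 (n ≥ 5 for second moments); smaller samples raise an
undefined-moments error.

### Sampler

The default sampler is a two-block Gibbs scheme on the exact
conditionals μ|σ²,y ~ normal(ȳ, σ²/n) and
σ²|μ,y ~ Inv-Gamma((n−1)/2, S(μ)/2), with rejection of draws outside
the prior box. Because each block is drawn exactly from its
conditional and the conditional of μ does not depend on the previous
μ, the chain mixes essentially in one step: R-hat < 1.01 and effective
sample sizes near the raw draw count at default settings. A
random-walk Metropolis sampler over (μ, σ) with proposal scales
2.4·s/√n and 2.4·s/√(2n) targets the same posterior and is available
via `McmcConfig(sampler="metropolis")` to demonstrate
sampler-independence; it is slower-mixing and exists for validation,
not production.

Defaults: 5 chains × 21,000 draws, burn-in 1,000 → 100,000 retained
draws. Chains are initialised overdispersed around the sample mean.
All randomness flows from a single integer seed through
`numpy.random.default_rng` (PCG64), so runs are bit-reproducible across
platforms.

### Derived quantities

Per retained draw k:

* attainment probability pₖ = Φ((L−μₖ)/σₖ) with L the administered
  dose (2.0 mL/kg default) — in enhancement space the upper tail
  Φ((μₖ−T)/σₖ) is used instead;
* coverage dose qₖ = μₖ + z(c)·σₖ with c the coverage target (0.95
  default) and z the standard-normal quantile. By construction,
  plugging qₖ back into the per-draw attainment returns exactly c.

Summaries are the mean ± SD of the per-draw values with central 95%
credible intervals, matching the mean ± SD presentation convention of
clinical protocol studies. The delta-method approximation
SD(p) ≈ φ(z)·√((1+z²/2)/n), z = (L−mean)/sd, provides an analytic
cross-check of the MCMC spread.

The headline probabilities are computed in required-volume space.
A secondary fit in enhancement (HU) space is reported alongside: the
two agree closely for the aorta but can differ for the parenchyma,
where the reciprocal transform makes the volume distribution
right-skewed relative to the enhancement distribution; reporting both
makes that model sensitivity visible rather than hiding it.

### Diagnostics

Split-chain Gelman–Rubin R-hat is implemented directly (each chain
halved; R̂ = √(((m−1)/m·W + B/m)/W) over the half-chains) and
cross-checked against ArviZ's classic split R-hat in the tests;
effective sample size comes from `arviz.ess`. The pipeline warns when
any R-hat exceeds 1.01.

## Synthetic cohorts

The generator emulates the study conditions: two arms of n = 100, a
fixed 2.0 mL/kg administered dose, and enhancement distributions with
the published arm moments (aorta HAP 340.9 ± 51.4 HU at 120 kVp,
395.9 ± 65.1 at 100 kVp; parenchyma PVP 57.8 ± 11.8 and 73.9 ± 15.5 HU).
Enhancement is drawn from a normal truncated below at 10% of the mean —
published histograms of such cohorts are unimodal and roughly
symmetric, and the floor prevents non-physical near-zero enhancement
from exploding the reciprocal transform. With moment matching on
(the default), samples are affinely rescaled so the sample mean and
n−1 SD hit the arm moments to machine precision, making the default
run a reproduction of the published summary statistics; a
`--no-moment-match` flag gives honest sampling variability instead.

Right/left hepatic lobes are generated as the patient's parenchymal
enhancement ± a symmetric offset (SD 3 HU), so equal-weight lobe
averaging recovers the drawn value exactly while the averaging code
path is exercised. Unenhanced baselines (aorta 45 ± 5 HU, parenchyma
58 ± 6 HU) and demographics (age ~69 ± 10 y, weight ~55 ± 10 kg, ~60%
male — plausible for elderly thin adults with chronic liver disease)
are plumbing for schema realism: baselines cancel in the differences
and demographics never feed the inference. The two arms are generated
independently.

What the generator does **not** emulate: the mild right-skew and
heavy tails of real enhancement distributions, inter-patient
correlates (weight, lean body mass, cardiac output, liver function),
scanner/ROI measurement noise, or patients appearing in both arms.
Consequently, passing tests demonstrate correctness of the statistical
machinery under the stated distributional conditions, not that a real
cohort would reproduce the published per-patient attainment counts;
in particular the real parenchymal volume spread at 120 kVp is wider
than a truncated-normal enhancement model can produce, which is why
the full-pipeline parenchymal probability (~69%) sits above the
volume-moment plug-in value (~65%).

## Numerical choices and problem sizes

* Moment matching uses the n−1 (sample) SD convention throughout,
  consistent with the oracle formulas.
* z(0.95) is the standard-normal quantile (1.6449), not a t quantile:
  the coverage dose is a population percentile given (μ, σ), not a
  predictive interval.
* Ties at the attainment threshold count as failures (strict ">").
* Degenerate inputs fail loudly: zero-variance data, prior boxes
  excluding the sample mean, empty cohorts, all-excluded transforms.
* Test-suite MCMC runs use reduced chain counts/lengths (e.g. 4 × 3,000)
  chosen so Monte-Carlo error is far below the tolerances being
  asserted; the sampler-vs-oracle equivalence check standardises every
  comparison by its exact MC standard error and bounds the family of
  ~220 z-scores (≤ 1% beyond 3 SE, none beyond 5 SE), the appropriate
  multiplicity-aware form of a per-quantity 3-SE check.
* The parameter-recovery study uses 200 replicates of n = 50 at
  (μ*, σ*) = (1.7, 0.3) mL/kg with 2 × 2,750-draw chains per replicate.

## Known limitations

* Linear dose–enhancement proportionality ignores saturation and
  timing effects; it is the standard first-order model and the only
  form the printed summaries identify.
* No covariate adjustment (weight, lean body mass, cardiac output),
  no hierarchical structure, no model comparison.
* The normal model for required volumes is an approximation to a
  reciprocal-of-truncated-normal; the package exposes both volume- and
  enhancement-space fits precisely because the choice matters at the
  parenchymal spread observed at 120 kVp.
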