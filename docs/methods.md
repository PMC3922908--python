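# Methods

## Model and estimation

The measurement model is a second-order confirmatory factor model for 22
Likert items on five constructs (SUS, SER, BEN, BAR, CTA), each item
loading on exactly one construct.  A single second-order factor HB
("health belief") drives the five constructs, and one directed structural
path BAR → CTA lets perceived barriers influence attention to cues, on the
hypothesis that respondents who see more barriers attend less to action
cues.  The implied covariance is

    Σ(θ) = Λ Φ Λᵀ + Θ,   Φ = (I − B)⁻¹ (γγᵀ + Ψ) (I − B)⁻ᵀ,  Var(HB) = 1.

**Identification.**  Var(HB) = 1 and one marker loading per first-order
construct fixed to 1 (the first item of each construct).  This leaves all
five second-order coefficients γ free, which matters because the BAR
coefficient is expected to be negative and small.  The fully standardized
solution (all latent and observed variances 1) is computed after
estimation:

    λ*_i = λ_i·sd(F_k(i))/sd(y_i),  γ*_k = γ_k/sd(F_k),
    β* = β·sd(F_BAR)/sd(F_CTA),     sd(F_k) = √Φ_kk,  sd(y_i) = √Σ_ii.

**Optimization.**  The normal-theory discrepancy
F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p is minimized with L-BFGS-B using
analytic gradients (tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹)·∂Σ/∂θ] assembled in closed form
for loadings, γ, structural coefficients and log-variances).  Variances
are parameterized on the log scale, which enforces positivity; solutions
with a variance below 1e−6 or a standardized coefficient beyond ±1 are
flagged as Heywood cases rather than silently accepted.  Five starting
points (one deterministic heuristic start plus four jittered copies) are
tried and the best minimum kept; convergence is declared when the
gradient's infinity norm falls below 1e−6.  On the default model the fit
takes well under a second, so multiple starts are cheap insurance against
local minima.

**Test statistic and indices.**  χ² = (n−1)·F_ML with
df = p(p+1)/2 − q (q = 50 free parameters for the default model, so
df = 203).  RMSEA = √(max(χ²−df,0)/(df(n−1))); its 90% interval inverts
the noncentral χ² CDF by Brent root-finding on the noncentrality.  The
independence baseline Σ₀ = diag(S) (df₀ = 231) feeds NFI, CFI and IFI;
GFI/AGFI use the standard ML forms on (S, Σ).  With 1–5 scores the
analysis treats items as continuous (classical normal-theory ML on the
sample covariance); no polychoric option is provided in this version, and
the known consequence — standardized loadings attenuated relative to the
underlying continuous responses — is asserted as a property of the
implementation rather than "corrected".

**Total effects and scoring.**  Factor-level standardized total effects
are (I − B*)⁻¹γ*, i.e. γ*_k for constructs without incoming paths and
γ*_CTA + β*γ*_BAR for CTA.  Item weights W_i = λ*_i · TE*(HB → F_k(i))
define the CFA-weighted score WHBS = Σ W_n·IS_n over raw 1–5 scores; the
barrier items' negativity is carried entirely by their weights.  The
simple sum score subtracts the raw barrier total from the sum of the
other 18 items, which makes its floor −2 and its ceiling 70; a re-keying
variant (6 − IS) would shift but not re-order respondents, and the
subtraction form is implemented as the more literal reading of
"barrier items entered negatively".

**Reliability.**  Cronbach's α = k/(k−1)·(1 − Σvar(item)/var(total)) with
sample variances and listwise deletion per scale.  Barrier items enter on
their raw keying: α is invariant to reflecting a consistently keyed
scale.  Note α is *not* invariant to rescaling items by different
positive slopes (only to one common slope plus per-item shifts); the test
suite asserts the correct invariance.  Because "average reliability" of a
five-part questionnaire is ambiguous, the report carries both the
whole-scale α and the mean of the five subscale αs, labelled.

**Cohort comparison.**  Two-independent-sample t-test on post − pre
scores, pooled-variance by default (the classical reading of "independent
sample t-test") with a Welch option; 95% CI = difference ± t₀.₉₇₅,df·SE.
Intervals are reported (lower, upper) with lower ≤ upper.

## Synthetic-data generator

The generator is parameterized directly in the standardized metric: HB,
every first-order factor and every continuous item variable have unit
population variance (mean 0 at cohort shift 0), so published standardized
coefficients serve verbatim as generating values.  Disturbance variances
are derived from the unit-variance constraint in topological order of the
structural graph; for the default model the CTA disturbance is
1 − γ²_CTA − β² − 2γ_CTA·β·γ_BAR.  Configurations implying a nonpositive
variance are rejected with the offending parameter named.

Study conditions default to the published survey: pre cohort n = 843,
post cohort n = 1269, ordinal responses through symmetric thresholds
(−1.5, −0.5, 0.5, 1.5) onto 1–5 (chosen for interior mass on all five
categories; the instrument itself fixes no thresholds), and a
post-intervention shift δ of the HB mean.  δ = 0.3 latent SD is the
default: a moderate effect consistent with a clearly significant but not
extreme improvement at these sample sizes.  Missingness is MCAR per cell
(default rate 0; `inject_missing` or `missing_rate` enables it) because
only listwise deletion, not a mechanism, is part of the analysis
contract.  Ages (uniform 15–18) and gender (Bernoulli 0.5) are nuisance
metadata and never modeled.

The reference coefficient set uses the published standardized solution:
γ = (0.72, 0.84, 0.87, −0.18, 0.60), β = 0.35, and loadings equal to each
item's published total effect divided by its construct's total effect.
One wrinkle: item 22's printed total effect (0.54) marginally exceeds the
implied construct-level total effect for CTA (0.60 + 0.35·(−0.18) =
0.537), presumably from rounding, which would imply a loading above 1.
Loadings are therefore capped at 0.99; the capped item's regenerated
total effect (≈ 0.53) remains within the recovery tolerance used
throughout (±0.02).

**What the generator does not emulate:** acquiescence and social
desirability response styles, cross-loadings, MNAR missingness,
measurement non-invariance between cohorts, and clustering by class or
school.  Passing recovery and calibration tests therefore show that the
estimator and scoring pipeline are correct under the assumed latent
model, not that the model describes any particular real survey.

## Numerical choices and edge cases

- Covariance computations use listwise-complete rows and ddof = 1.
- F_ML evaluation rejects non-PD matrices via Cholesky; the optimizer
  returns +inf for non-PD Σ(θ) proposals, steering the line search back.
- The RMSEA CI lower bound is 0 whenever the central χ² CDF at the
  observed statistic is below 0.95 (the conventional boundary case).
- Fit indices are skipped (not fabricated) when df ≤ 0, as in
  just-identified or deliberately overparameterized submodels used by
  tests.
- Determinism: every stage takes a seed; study generation spawns
  independent child streams per cohort from one master seed, so pre/post
  draws never share state, and reruns are byte-identical.

## Benchmark problem sizes

Parameter recovery uses n = 50,000 continuous-mode respondents (sampling
error ≈ 0.005 per standardized coefficient, comfortably inside the ±0.02
recovery band).  Sampling-calibration suites use 100–400 replicates at
n = 843–5,000, sizes at which the χ² mean ≈ df check and the nominal 5%
null rejection rate are sharp enough to catch implementation errors while
keeping the full test suite around a minute.
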