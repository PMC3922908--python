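# hbmscore

Evaluation of health-education interventions through Health Belief Model
(HBM) questionnaires: second-order confirmatory factor analysis,
CFA-weighted scale scoring, reliability analysis, and pre/post cohort
comparison — with a synthetic-data generator so the whole pipeline is
testable end to end without survey data.

## The problem

Injury-prevention programmes are often evaluated with a multi-item Likert
questionnaire built on the HBM's five constructs — perceived
susceptibility (SUS), perceived seriousness (SER), perceived benefits
(BEN), barriers to action (BAR) and cues to action (CTA) — administered
before and after the intervention.  The traditional evaluation sums the
item scores (the *simple sum score*, SSS), which weights a noisy item the
same as a highly informative one.  A measurement-model alternative fits a
confirmatory factor model and scores each respondent with weights
proportional to how strongly each item reflects the underlying health
belief (the *CFA-weighted score*, CFAWS).

`hbmscore` implements both for a 22-item instrument (5 SUS, 4 SER, 5 BEN,
4 BAR, 4 CTA items on a 1–5 scale).

## The model

A second-order factor model with a structural path between two first-order
constructs:

```
y_i   = λ_i F_k(i) + ε_i,           Θ = Cov(ε) diagonal   (22 items)
F_k   = γ_k HB + Σ_j B_kj F_j + ζ_k, Ψ = Cov(ζ) diagonal  (5 constructs)
Var(HB) = 1,   B: BAR → CTA only
```

implying `Σ(θ) = Λ Φ Λᵀ + Θ` with `Φ = (I−B)⁻¹(γγᵀ + Ψ)(I−B)⁻ᵀ`.
Estimation minimizes the normal-theory discrepancy
`F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p` with analytic gradients; the model
χ² is `(n−1)·F_ML` and the usual index battery (RMSEA with 90% CI, GFI,
AGFI, NFI, CFI, IFI) is reported.  The per-item **total effect** of health
belief,

```
W_i = λ*_i · TE*(HB → F_k(i)),   TE*(HB → CTA) = γ*_CTA + β*·γ*_BAR
```

(starred quantities are fully standardized), is the CFAWS weight vector:
`WHBS = Σ_n W_n · IS_n` over the raw item scores `IS_n`.  The SSS enters
barrier items negatively: `HBS = Σ_{non-BAR} IS_n − Σ_{BAR} IS_n`.

Because real survey data for such programmes are rarely shared, the
package ships a generator that simulates Likert responses from this exact
latent model in the standardized metric, including a post-intervention
upward shift `δ` of the health-belief factor, discretization to the 1–5
scale, and MCAR missingness.  Its default coefficients are a published
standardized solution for this instrument (second-order coefficients
0.72, 0.84, 0.87, −0.18, 0.60; BAR→CTA 0.35), making parameter-recovery
benchmarks meaningful.

## Worked example

```python
import hbmscore as hs

cfg = hs.reference_config(seed=21)        # pre n=843, post n=1269, delta=0.3
pre, post = hs.generate_study(cfg)

result = hs.fit(post, seed=21)            # CFA on the larger survey
w = result.total_effects                  # CFAWS weights

for method, scorer in (("cfaws", lambda t: hs.cfaws_score(t, w)),
                       ("sss", hs.sss_score)):
    comp = hs.compare_cohorts(scorer(pre), scorer(post), method=method)
    print(method, round(comp.mean_difference, 2),
          (round(comp.ci_lower, 2), round(comp.ci_upper, 2)),
          f"p={comp.p_value:.2g}")
```

prints

```
cfaws 1.86 (1.16, 2.57) p=2.4e-07
sss 2.99 (1.82, 4.16) p=6.4e-07
```

Both scoring rules detect the simulated post-intervention improvement in
health belief; the CFA-weighted interval is narrower relative to the mean
difference it brackets (width/difference 0.76 vs 0.79) because the weights
emphasize items that carry more of the common factor.  The same pipeline
is available from the shell:

```sh
hbmscore run --seed 21 --out results/demo
hbmscore simulate --seed 1 --out data/        # or stage by stage
hbmscore fit --data data/post.csv --out fit.json
```

`examples/` contains one short script per capability (simulation, CFA
fitting, reliability, scoring/comparison).

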