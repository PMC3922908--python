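"""Fit the second-order CFA and inspect the standardized solution.

Simulates a post-intervention survey, fits the five-construct model with
the BAR -> CTA structural path by maximum likelihood, and prints the
standardized second-order coefficients, the fit-index battery and the
per-item total effects (the CFA score weights).
"""

import numpy as np

import hbmscore as hs

cfg = hs.reference_config(seed=7, n_post=5000)
_, post = hs.generate_study(cfg)

result = hs.fit(post, seed=7)

print(f"n used (listwise complete): {result.n_used}")
print(f"chi-square = {result.chi_square:.2f} on df = {result.df}")
idx = result.fit_indices
print(f"RMSEA = {idx.rmsea:.4f} (90% CI {idx.rmsea_ci_lower:.4f}, "
      f"{idx.rmsea_ci_upper:.4f})")
print(f"GFI = {idx.gfi:.3f}  AGFI = {idx.agfi:.3f}  NFI = {idx.nfi:.3f}  "
      f"CFI = {idx.cfi:.3f}  IFI = {idx.ifi:.3f}\n")

print("standardized second-order coefficients (health belief -> construct):")
for f, g in zip(hs.FACTORS, result.gamma_std):
    print(f"  {f}: {g:+.3f}")
print(f"BAR -> CTA structural coefficient: {result.beta_std[0]:+.3f}\n")

print("total effects (CFA score weights), items 1-22:")
print(np.array2string(result.total_effects, precision=2, suppress_small=True))

# The recovered coefficients sit close to the generating standardized
# solution (0.72, 0.84, 0.87, -0.18, 0.60; BAR->CTA 0.35); barrier items
# carry small negative weights because their construct relates negatively
# to overall health belief.
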