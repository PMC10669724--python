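"""Regions-of-significance diagnostics for a fitted interaction.

Four indicators separate diathesis-stress from differential susceptibility:
Johnson-Neyman boundaries on the environment axis, the crossover point, the
proportion-of-interaction (PoI) and proportion-affected (PA) indices, and a
quadratic mis-specification probe; Holm's step-down correction guards the
family of interaction tests.
"""

from gxecross import poi_index, pa_index, holm_correction

# Desk-scale reconstruction from the published confirmatory fit: crossover
# C = 0.49, observed standardized home-supervision range (-4.31, 1.85).
res = poi_index(0.49, (-4.31, 1.85))
print(f"PoI = {res.poi:.4f} -> printed as {round(res.poi, 2)}")
print("Only ~7% of the between-line area lies on the 'for better' side of "
      "the crossover: far from the 0.50 a differential-susceptibility "
      "pattern would show, i.e. evidence for diathesis-stress.")

pa = pa_index(0.49, mode="normal")
print(f"\nPA  = {pa.pa:.4f} -> printed as {round(pa.pa, 2)}")
print("~31% of children (standard-normal environment beyond the crossover) "
      "sit on the 'good' side; PA >= 16% is the conventional floor for "
      "calling differential susceptibility, so PA alone does not rule "
      "either way.")

holm = holm_correction([0.005, 0.2, 0.8], alpha=0.05)
print(f"\nHolm critical value for the smallest of 3 p-values: "
      f"{holm.critical[0]:.4f}")
print("0.005 < 0.0167, so the focal interaction survives the sequential "
      "Bonferroni correction for testing three SNPs.")
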