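"""Translate ages between medaka months and human years.

Fits the through-origin quadratic Age_medaka = a*Age_human + b*Age_human^2
to five life-history hallmark pairs (sexual maturation, per-sex median
lifespan, per-sex maximum lifespan) and inverts the reference model at
the female estrogen-decline window.
"""

import telovita as tv

fit = tv.fit_model()
print(f"fitted model: a = {fit.a:.4f} months/year, b = {fit.b:.5f} months/year^2")
print(f"R2 about zero = {fit.r_squared:.4f} (no-intercept convention); "
      f"about the mean = {fit.r_squared_mean:.4f}")

ref = tv.reference_model()
for months in (8.0, 12.0):
    years = tv.medaka_to_human(ref, months)
    print(f"medaka {months:.0f} months  ->  human {years:.1f} years")
print("The 8-12 month window where female medaka estrogen declines maps to "
      "46-60 human years, the menopausal range.")
print(f"note on the reference model: {ref.notes[0]}")
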