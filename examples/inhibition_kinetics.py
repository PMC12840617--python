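"""Discriminate inhibition modes and estimate Ki from velocity data.

Simulates initial-velocity measurements for a competitive and a
non-competitive inhibitor on the standard assay design (substrate
0.025-0.4, inhibitor 0/400/800 uM), fits all candidate inhibition models
globally, and compares the selected Ki with the closed-form value from the
printed apparent parameters.
"""

from peptiforge import (
    NoiseModel,
    fit_ic50,
    fit_inhibition_global,
    gen_kinetics,
    ki_competitive,
    ki_noncompetitive,
    lineweaver_burk,
    select_model,
)

KM, VMAX = 0.2684, 1.4428  # uninhibited Michaelis-Menten parameters

for truth, ki_true in (("competitive", 709.0), ("noncompetitive", 186.0)):
    data = gen_kinetics(truth, KM, VMAX, Ki=ki_true, replicates=2,
                        noise=NoiseModel(velocity_cv=0.02), seed=5)
    fits = fit_inhibition_global(data)
    best = select_model(fits)
    print(f"\ngenerated as {truth} (Ki = {ki_true} uM), 2% noise:")
    print(f"  selected model: {best.model}")
    print(f"  Km = {best.Km:.4f}, Vmax = {best.Vmax:.4f}, Ki = {best.Ki:.1f} uM")
    print("  AICc ranking:", ", ".join(f"{f.model} ({f.aicc:.1f})" for f in fits))
# The global fit shares Km, Vmax and Ki across all inhibitor levels; AICc
# with a parsimony window picks the mode, replacing the by-eye reading of
# Lineweaver-Burk intersection geometry.

# closed-form constants from the printed apparent parameters
print("\nclosed-form Ki from printed apparent parameters at I = 400 uM:")
print(f"  competitive  (Km 0.2684 -> 0.4196): Ki = {ki_competitive(0.2684, 0.4196, 400):.0f} uM")
print(f"  noncompetitive (Vmax 1.4428 -> 0.4580): Ki = {ki_noncompetitive(1.4428, 0.4580, 400):.0f} uM")

# Lineweaver-Burk diagnostics: a shared y-intercept marks competitive
# inhibition, a shared negative x-intercept marks non-competitive.
lines = lineweaver_burk(gen_kinetics("noncompetitive", KM, VMAX, Ki=186.0))
print("\nnoiseless noncompetitive double-reciprocal x-intercepts:")
for level, line in lines.items():
    print(f"  I = {level:5.0f} uM: x-intercept {line.x_intercept:.3f} (= -1/Km)")

# dose-response: IC50 from residual-activity percentages
import numpy as np

conc = np.array([62.5, 125, 250, 500, 1000, 2000.0])
activity = 100.0 / (1.0 + conc / 321.5)
fit = fit_ic50(conc, activity)
print(f"\nIC50 fit on an exact logistic curve: {fit.ic50:.1f} uM (Hill {fit.hill:.2f})")
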