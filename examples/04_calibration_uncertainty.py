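"""Calibration-curve prediction uncertainty, formula vs simulation.

Fits the 5-level x 3-replicate calibration line, evaluates the inverse
prediction standard uncertainty for the mean of 6 replicate sample
injections, and cross-checks the formula by brute-force re-simulation.
"""

from mubudget import (
    SyntheticDesign,
    fit_calibration,
    gen_calibration,
    prediction_u,
    recovery_u_cx,
)

design = SyntheticDesign()
points = gen_calibration(design, rng=0)
reg = fit_calibration(points["concentration"], points["response"])
print(
    f"fit: slope {reg.slope:.2f}, intercept {reg.intercept:.3f}, "
    f"Sres {reg.sres:.4f}, n {reg.n}, C_bar {reg.c_bar:.3f}, SSDx {reg.ssdx:.3f}"
)

u_cx = prediction_u(reg, p=6, cx=0.2005)
print(f"u(Cx) at 0.2005 mg/mL with p = 6 replicates: {u_cx:.6f} mg/mL")
print(f"relative to the 0.2 mg/mL working level:      {u_cx / 0.2005:.5f}")
print()

rec = recovery_u_cx(design, p=6, cx_true=0.2, repetitions=2000, rng=1)
print(
    f"recovery oracle: empirical sd {rec.empirical_sd:.6f} vs formula "
    f"{rec.formula_u:.6f} (ratio {rec.ratio:.3f})"
)
print()
print(
    "The formula's ~0.0004 mg/mL (relative 0.002) is the single largest\n"
    "budget entry after the sample volume; the simulation ratio near 1\n"
    "confirms the closed-form standard error of the inverse prediction."
)
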