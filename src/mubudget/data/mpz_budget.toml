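# Uncertainty budget for the HPLC-UV assay of Metopimazine (MPZ) in
# injectable solution.
#
# Content model:
#   C% = (At/Ast) * (Pt/Vt1) * (Vp/Vt2) * (Vt/VSample) * P * delta_r * Cx * 10
# The constant 10 absorbs the dose ratio (0.1 mL/mg, i.e. 1 mL per 10 mg)
# and the percent scaling; P is the purity as a dimensionless fraction.
#
# reported_content is the content value printed on the published budget
# sheet (99.41).  Evaluating the model at the nominal values gives 99.700;
# the printed value instead equals (At/Ast)^2 * P * 100 to 4 significant
# figures.  Both are kept: the engine always computes its own content and
# carries the published figure as metadata so the printed budget can be
# reproduced verbatim.
#
# delta_r pools the repeatability of the whole procedure (3 runs x 6
# replicates); Cx is the calibration-curve prediction factor — its standard
# uncertainty 0.0004 is in mg/mL at the 0.2 mg/mL working level, hence the
# directly-supplied relative uncertainty 0.002 (relative_effect = true).
# u(At) = u(Ast) = 0.0022 is the chromatographic system uncertainty taken
# as a given Type B value from the system-suitability study.
#
# The purity distribution bounds are the certificate interval
# 0.9999 +/- 0.0001 (rectangular), consistent with u(P) = 0.000058.

name = "mpz-hplc-uv"
reported_content = 99.41

[model]
numerator = ["At", "Pt", "Vp", "Vt", "P", "delta_r", "Cx"]
denominator = ["Ast", "Vt1", "Vt2", "VSample"]
constant = 10.0

[quantities.delta_r]
value = 1.0
unit = ""
standard_uncertainty = 0.0005
relative_uncertainty = 0.0005
relative_effect = true
dof = 17

[quantities.Cx]
value = 1.0
unit = ""
standard_uncertainty = 0.0004  # mg/mL at the 0.2 mg/mL working level
relative_uncertainty = 0.002
relative_effect = true
dof = 13

[quantities.At]
value = 70.509
unit = "area"
standard_uncertainty = 0.0022
dof = 5

[quantities.Ast]
value = 70.714
unit = "area"
standard_uncertainty = 0.0022
dof = 5

[quantities.Pt]
value = 100.0
unit = "mg"
standard_uncertainty = 0.01155

[quantities.Vt1]
value = 100.0
unit = "mL"
standard_uncertainty = 0.06339

[quantities.Vt2]
value = 25.0
unit = "mL"
standard_uncertainty = 0.02034

[quantities.Vp]
value = 5.0
unit = "mL"
standard_uncertainty = 0.00659

[quantities.Vt]
value = 100.0
unit = "mL"
standard_uncertainty = 0.06339

[quantities.VSample]
value = 2.0
unit = "mL"
standard_uncertainty = 0.0042

[quantities.P]
value = 0.9999
unit = ""
standard_uncertainty = 0.000058

[distributions.delta_r.repeatability]
family = "normal"
mean = 1.0
sd = 0.0005

[distributions.Cx.calibration]
family = "normal"
mean = 0.2
sd = 0.0004

[distributions.At.sst]
family = "normal"
mean = 70.509
sd = 0.0022

[distributions.Ast.sst]
family = "normal"
mean = 70.714
sd = 0.0022

[distributions.VSample.calibration]
family = "triangular"
a = 1.99
b = 2.01

[distributions.VSample.temperature]
family = "rectangular"
a = 1.99832
b = 2.00168

[distributions.Pt.calibration]
family = "rectangular"
a = 99.98
b = 100.02

[distributions.Vt1.calibration]
family = "triangular"
a = 99.9
b = 100.1

[distributions.Vt1.temperature]
family = "rectangular"
a = 99.916
b = 100.084

[distributions.Vt2.calibration]
family = "triangular"
a = 24.96
b = 25.04

[distributions.Vt2.temperature]
family = "rectangular"
a = 24.979
b = 25.021

[distributions.Vp.calibration]
family = "triangular"
a = 4.985
b = 5.015

[distributions.Vp.temperature]
family = "rectangular"
a = 4.9958
b = 5.0042

[distributions.Vt.calibration]
family = "triangular"
a = 99.9
b = 100.1

[distributions.Vt.temperature]
family = "rectangular"
a = 99.916
b = 100.084

[distributions.P.certificate]
family = "rectangular"
a = 0.9998
b = 1.0000
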