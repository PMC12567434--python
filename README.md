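# mubudget

Measurement-uncertainty budgets for chromatographic drug assays: bottom-up
GUM propagation through a product-form content model, Monte Carlo
distribution propagation (GUM Supplement 1), and the numerical-tolerance
validation of the GUM interval against the Monte Carlo coverage interval.

The package is aimed at pharmaceutical quality-control and analytical-method
scientists who must report an assay result together with its expanded
uncertainty (ISO/IEC 17025). It ships a complete worked budget: the HPLC-UV
assay of Metopimazine (an antiemetic) in injectable solution, whose content
model is

```
C% = (At/Ast) · (Pt/Vt1) · (Vp/Vt2) · (Vt/VSample) · P · δr · Cx · const
```

with peak areas `At`/`Ast`, reference mass `Pt`, the dilution-chain volumes,
purity `P`, and the unit-valued relative-effect factors `δr` (pooled method
repeatability) and `Cx` (calibration-curve prediction).

## The methods in one paragraph

For a pure product model the GUM law of propagation reduces to quadrature of
relative standard uncertainties, `u(C)/C = sqrt(Σ (u(xᵢ)/xᵢ)²)`, expanded
with a coverage factor `k = 2` (≈95%) or a Welch–Satterthwaite Student-t
factor. Each budget entry is evaluated from its own evidence: Type A
statistics (`s/√m`), rectangular/triangular Type B conversions (`a/√3`,
`a/√6`), glassware calibration + temperature-expansion components, the
inverse-prediction standard error of the calibration line
`u(Cx) = (Sres/a₁)·sqrt(1/p + 1/n + (Cx−C̄)²/SSDx)`, and pooled run
repeatability `SR = Sr/√n`. The Monte Carlo route samples every input from
its assigned distribution, evaluates the model per trial, and reads the
equal-tailed 95% coverage interval off the output sample. The two routes are
compared within the Supplement-1 tolerance `δ = 0.5·10^l` (where
`u = c·10^l`, `c` a 1–2 digit integer): the GUM result is validated when both
interval-endpoint differences stay below δ.

## Worked example

```python
from mubudget import gum_budget, mcs_budget, mpz_budget, validate_gum_mcs

budget = mpz_budget()                      # packaged assay budget
gum = gum_budget(budget)                   # bottom-up quadrature
mcs = mcs_budget(budget, m=1_000_000, seed=0)
vr = validate_gum_mcs(gum, mcs)
print(f"C = ({gum.content:.2f} ± {gum.expanded_u:.2f})% (k = {gum.k:g})")
print(f"MCS: sd {mcs.sd:.4f}, k_emp {mcs.k_emp:.4f}, "
      f"interval [{mcs.y_low:.4f}, {mcs.y_high:.4f}]")
print(f"delta {vr.delta:g}, d_low {vr.d_low:.4f}, d_high {vr.d_high:.4f}, "
      f"validated: {vr.validated}")
```

prints

```
C = (99.70 ± 0.69)% (k = 2)
MCS: sd 0.3438, k_emp 1.9532, interval [99.0304, 100.3737]
delta 0.05, d_low 0.0176, d_high 0.0138, validated: True
```

The combined relative uncertainty is 0.0034 (u(C) ≈ 0.34%), dominated by the
sample volume (share 0.37) and the calibration prediction (0.34); the Monte
Carlo sd agrees with the GUM value to 0.03%, the output is essentially
Gaussian (empirical k ≈ 1.95), and both interval endpoints differ by less
than the tolerance δ = 0.05 — the linearized GUM treatment is validated for
this assay. The published budget sheet carries a content of 99.41 with
u = 0.3427 / U = 0.6853; evaluating the model at the sheet's own nominal
values gives 99.700 instead, so the engine always reports its computed
content and keeps the sheet's figure as metadata
(`gum_budget(budget, content="reported")` reproduces the printed numbers).

The `examples/` directory holds one narrative script per capability (GUM
budget, Monte Carlo + convergence, validation, calibration uncertainty,
synthetic raw-data study); each prints the numbers above with a short
explanation. The same pipeline is available from the shell:

```
mubudget report --out-dir out --trials 1000000 --seed 0
```

## Layout

- `src/mubudget/budget_model.py` — content model, quantities, config I/O
- `src/mubudget/evaluators.py` — Type A/B, volumes, calibration, repeatability
- `src/mubudget/gum.py` — relative quadrature, coverage factors, contributions
- `src/mubudget/mcs.py` — distribution sampling, summaries, convergence
- `src/mubudget/validation.py` — Supplement-1 tolerance test
- `src/mubudget/synthetic.py` — synthetic raw-data generators and oracles
- `src/mubudget/report.py`, `cli.py` — report tables and the thin CLI
- `docs/methods.md` — model assumptions, defaults and numerical choices
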