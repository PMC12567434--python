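# Methods

## Measurand and model

The measurand is the content `C` of a drug substance in an injectable
solution, in percent of label claim. The measurement equation is a pure
product/quotient,

    C% = (At/Ast) · (Pt/Vt1) · (Vp/Vt2) · (Vt/VSample) · P · δr · Cx · const,

where the constant absorbs the dose ratio (0.1 mL/mg for a 10 mg/mL
formulation) and the percent scaling. Purity `P` is stored as a
dimensionless fraction (0.9999) and enters as a plain multiplier, so no
`/100 · ×100` pair appears twice. `δr` and `Cx` are *relative-effect*
factors: their nominal value is 1 and they exist only to carry, on a relative
scale, the pooled repeatability of the whole procedure and the uncertainty of
the concentration predicted from the calibration line. By construction the
dilution chain cancels at the nominal design — with equal peak areas the
model evaluates to `P · 100` exactly — which is asserted as an invariant.

Assumptions inherited from this model class: all inputs are uncorrelated
(the covariance term of the general propagation law is out of scope), the
model is smooth and effectively linear over the spread of its inputs, and
relative uncertainties are small (≲1%), so relative quadrature and the
first-order law agree.

### Content-value caveat of the packaged budget

Evaluating the packaged budget at its nominal values gives `C = 99.700`.
The published budget sheet prints `C = 99.41`, which instead equals
`(At/Ast)² · P · 100` to four significant figures — the sheet appears to have
folded the area ratio into the `Cx` factor a second time. The engine never
guesses: it reports its own computed content, carries the sheet's figure as
`reported_content` metadata, and `gum_budget(budget, content="reported")`
reproduces the printed `u(C) = 0.3427` / `U = 0.6853` for comparison with the
sheet. The end-to-end pipeline (`report` command) uses the self-consistent
computed content for both the GUM and MCS intervals so the validation
compares like with like.

## Uncertainty evaluation

* **Type A**: `u = s/√m`, `ν = m − 1`, refused below two observations.
* **Type B**: rectangular half-width `a/√3`; triangular `a/√6`. Glassware
  calibration tolerances are triangular (values near the mark most likely);
  temperature excursions rectangular. The temperature half-width is
  `V·ΔT·α` with the water expansion coefficient `α = 2.1e-4 /°C` and a
  laboratory excursion `ΔT = 4 °C` by default.
* **Volumes**: `u(V) = sqrt(u_cal² + u_temp²)`; a dilution chain combines
  item relatives in quadrature. Filling repeatability is *not* added per
  item — it is already contained in the pooled method repeatability `δr`,
  and double counting is deliberately avoided.
* **Calibration prediction**: unweighted OLS through the normal equations
  (homoscedastic residuals are an assumption of the design; no weighting, no
  outlier rejection). `u(Cx) = (Sres/a₁)·sqrt(1/p + 1/n + (Cx−C̄)²/SSDx)`;
  strictly decreasing in `p` and `n`, minimal at `C̄`.
* **Repeatability**: dof-weighted ANOVA pooling of within-run variances
  across runs; `SR = Sr/√n_total` by default (`n_total = runs × replicates`),
  with a `per_run` divisor option for the uncertainty of a single future run
  mean.
* **Chromatographic precision**: the system-suitability summary reports mean,
  sd, CV% and sd-of-mean per channel with the usual acceptance limits
  (area CV < 2.0%, retention CV < 1.0%). The packaged budget's
  `u(At) = u(Ast) = 0.0022` is a given Type B value from that study; it is
  not derivable as a quadrature of the two sd-of-means and is therefore
  stored, not recomputed.

## GUM combination

`u_rel = sqrt(Σ relᵢ²)` over the eleven budget terms; `u(C) = u_rel · C`;
`U = k·u(C)` with `k = 2` by default (the convention for ≈95% coverage under
normality). Welch–Satterthwaite effective degrees of freedom are opt-in:
`ν_eff = u⁴/Σ uᵢ⁴/νᵢ` (infinite-dof components drop from the denominator),
truncated down to an integer for the two-tailed 97.5% t-quantile.
Contribution shares are variance shares `relᵢ²/Σ rel²`, Pareto-ordered with
cumulative percentages; they sum to 1 by construction. A central
finite-difference propagation (relative step 1e-6, chosen for a smooth,
scale-free model) is kept as an internal oracle: on product models it must
agree with the quadrature to ≲1e-6 relative, and the test suite enforces
this. In the numeric path each input's uncertainty enters in model units as
`relative_uncertainty × value`, which is what makes the relative-effect
factors consistent across both routes.

## Monte Carlo propagation

Distribution families: normal (`mean`, `sd`), rectangular (uniform on
`[a, b]`), triangular generated as `a + (b−a)/2·(U₁+U₂)` — the
sum-of-two-uniforms construction. Each input's trial value is

    x = x_nominal · (1 + Σ_k (draw_k − center_k)/center_k),

which sums independent components (e.g. a volume's calibration and
temperature rows) as deviations around the shared nominal, and reduces
distributions stated on another physical scale (the calibration-prediction
factor, normal around 0.2 mg/mL while the model factor is unit-valued) to
the correct multiplicative perturbation `draw/0.2`.

The summary reports mean, median, sd, skewness (third standardized central
moment) and the equal-tailed percentile interval at 95% coverage; the
expanded uncertainty is the interval half-width and the empirical coverage
factor `k_emp` its ratio to the sd. Equal-tailed is the default because the
output is near-symmetric and it reproduces `U ≈ k·u` for such outputs; a
shortest-interval option exists. Intervals are refused below 1000 samples
(moments only). A single seedable `numpy.random.Generator` drives all
sampling; symbols are traversed in model order and components in sorted name
order, so a fixed seed gives bit-identical results.

Trial count: `M = 10⁶` for reported results (about a second of compute,
quantile standard error ≈ 0.003 content-% per endpoint). The convergence
study tabulates interval width over ascending `M` and flags stability when
the width change drops below a tolerance. The stabilization tolerance is
stated **in the measurand's units** (default 0.01 content-%): quantile
sampling theory puts the sd of the width change between `M = 10⁵` and `10⁶`
at ≈0.004 content-% (≈0.3% of the width) for this budget, so an absolute
0.01 is the sharpest claim such a study can reliably certify, whereas a
*relative* 0.01% (or even 0.1%) tolerance would sit far inside the sampling
noise and fail for most seeds regardless of implementation. Both absolute
and relative changes are reported.

## GUM-vs-MCS validation

`u = c·10^l` with `c` an integer mantissa of 1–2 significant digits; the
mantissa is rounded half away from zero using decimal arithmetic so printed
half-way values (0.95 → 1·10⁰) behave as a reader expects — this matters
because δ jumps an order of magnitude at mantissa boundaries. Tolerance
`δ = 0.5·10^l`; GUM bounds `y ∓ U`; verdict validated iff both
`d_low = |L_low − y_low|` and `d_high = |L_high − y_high|` are below δ.
Both differences, δ, `c`, `l` and the verdict are always reported so the
comparison table can be regenerated verbatim.

## Synthetic data

The generators emulate the three raw-data surfaces the budget consumes, at
the summary level only (no chromatogram or peak-shape simulation):

* calibration: 5 levels × 3 replicates over 0.12–0.28 mg/mL (60–140% of the
  0.2 mg/mL working level, giving `SSDx = 0.048 (mg/mL)²` and `n = 15`),
  homoscedastic normal residuals;
* repeatability: 3 runs × 6 replicates of content determinations;
* system suitability: 6 injections of retention time and peak area.

Default true parameters mirror the packaged budget's observable summaries:
slope 352.5 response/(mg/mL) (so the response at the working level is ≈70.5,
matching the recorded peak areas; the slope itself is arbitrary because the
prediction uncertainty depends only on `Sres/a₁`), residual sd 0.287 (ratio
≈8.1e-4 mg/mL, reproducing `u(Cx) ≈ 0.0004`), within-run repeatability sd
0.05 on a ≈99.7 content scale (relative ≈5e-4, the budget's `u(δr)`), and
SST means/sds equal to the recorded series. What passing tests on these data
do **not** show: behaviour under heteroscedastic or drifting responses,
carry-over, integration artifacts, or non-normal noise — none of which the
budget model represents either.

`recovery_u_cx` is the parameter-recovery oracle for the prediction-
uncertainty formula: simulate a fresh calibration, fit, simulate `p`
replicate responses at a known true concentration, invert through the fitted
line, and compare the empirical sd of the predictions over ≥1000 repetitions
with the formula at the true parameters (the suite requires agreement within
10% at 2000 repetitions).

## Numerical and design choices

* Budget configs are TOML (read) and JSON (read/write); loading cross-checks
  every distribution assignment against the declared standard uncertainty
  (implied relative sd within 3%) and reports schema errors with the path of
  the offending entry.
* Degenerate inputs: zero half-widths give zero Type B uncertainty; constant
  observation series give zero Type A; near-constant Monte Carlo samples
  report zero skewness rather than cancellation noise; a singular
  calibration design (one distinct level) is rejected.
* Problem sizes used in the shipped tests and reports: `M = 10⁶` trials for
  headline Monte Carlo numbers, `10⁴/10⁵/10⁶` for the convergence study,
  2000 repetitions for the recovery oracle, 10⁵ draws for sampler moment
  checks — sizes at which every stochastic assertion has ≥3σ headroom.

## Known limitations

* Only product/quotient models with scalar constants and relative-effect
  factors; no general symbolic models, no correlated inputs.
* No adaptive Monte Carlo, no quasi-random sequences, no weighted or
  nonlinear calibration, no outlier rejection.
* The packaged budget's internal inconsistencies (content value, printed
  contribution percentages, the non-derivable `u(HPLC-UV)`) are carried as
  given metadata and documented above rather than silently "fixed".
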