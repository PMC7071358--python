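# Methods

This note records the statistical model behind `ironmr`, the numerical
conventions it fixes, what the synthetic-data generator does and does not
emulate, and the design choices made where more than one defensible
option existed.

## Model and estimators

Two-sample summary-data MR treats each genetic variant *j* as an
instrument: β̂<sub>j</sub> ± se(β̂<sub>j</sub>) is its association with
the exposure (SD units per effect allele, from one study) and
γ̂<sub>j</sub> ± se(γ̂<sub>j</sub>) its association with a binary outcome
(log-odds per allele, from another study). Under the instrumental-variable
assumptions each Wald ratio θ<sub>j</sub> = γ<sub>j</sub>/β<sub>j</sub>
identifies the same causal log-odds ratio per SD of exposure.

**Wald ratio SE.** The default is first-order,
se(θ<sub>j</sub>) = se(γ̂<sub>j</sub>)/|β<sub>j</sub>|, which ignores
exposure-side sampling error; with it, a ratio's z and p are exactly those
of the outcome association, so the same variant shows identical per-variant
p-values across exposures that share an outcome — a useful internal
consistency check on published per-variant tables. The second-order
(delta-method) SE, adding γ²se(β̂)²/β⁴, is available via
`wald_ratio(pair, order="second")` and is never smaller. The bundled
reference tables were evidently produced with first-order weights (their
per-variant p-values repeat across exposure columns), which is why it is
the default.

**IVW.** Fixed effects: θ̂ = Σwθ/Σw, se = (Σw)^(−1/2), w = se(θ)⁻².
Random effects use the *multiplicative* over-dispersion model: the SE is
scaled by φ = max(1, √(Q/(L−1))) with Q from Cochran's statistic, leaving
the point estimate unchanged and never shrinking the CI below the
fixed-effects one. The multiplicative (rather than additive DerSimonian–
Laird) form was chosen because it exactly regenerates the bundled
reference CIs — for the serum-iron → liver analysis the fixed SE 0.276
must be scaled by √(Q/2) = 2.06 to give the reference interval
(0.81, 7.45) — so it is what the original analysis software used.

**Weighted median.** Order the ratios θ<sub>(1)</sub> ≤ … ≤ θ<sub>(L)</sub>
with normalized weights p<sub>j</sub> and cumulative midpoints
s<sub>j</sub> = Σ<sub>k&lt;j</sub>p<sub>k</sub> + p<sub>j</sub>/2; the
estimate linearly interpolates the weighted empirical CDF at ½ (clamped to
the extreme order statistics when ½ falls outside [s₁, s<sub>L</sub>]).
The SE is a parametric bootstrap — θ<sub>j</sub>* ~ N(θ<sub>j</sub>,
se<sub>j</sub>), default 10,000 replicates, mandatory seed — and the CI is
normal (θ̂ ± 1.96·se) by default, with bootstrap-percentile CIs behind
`ci_method="quantile"` since it is not knowable which convention a given
published table used. The point estimate is independent of the bootstrap.

**MR-Egger.** Pairs are first oriented so every β<sub>j</sub> > 0
(flipping both betas of a pair is a no-op for the fit, verified by test);
then γ is regressed on β with weights 1/se(γ̂)² and a free intercept. A
nonzero intercept estimates the average directional pleiotropic effect;
the slope estimates the causal effect under InSIDE (pleiotropy
independent of instrument strength). Inference uses **normal quantiles**
with the unit-dispersion weighted-least-squares standard errors scaled by
φ′ = max(1, √(Q<sub>resid</sub>/(L−2))). With L = 3 instruments a Student
t with 1 degree of freedom would be essentially uninformative; the normal
convention is what reproduces the bundled reference intercept CI
(−1.124, −0.199), whose half-width equals 1.96 × the unit-dispersion SE.

**Heterogeneity.** Q = Σw(θ − θ̂<sub>fixed</sub>)², df = L − 1, p from the
chi-square upper tail, I² = max(0, (Q − df)/Q)·100. The I² CI is the
test-based interval on ln H (H² = Q/df) with the conventional large-Q
(Q > df + 1) and small-Q standard errors, truncated to [0, 100]. The CI
method is a convention choice — published tables rarely state theirs — so
the package treats the I² point value as the reproducible quantity and the
CI as indicative.

**Power.** se(θ̂) ≈ [n·R²·K(1−K)]^(−1/2) for an outcome study of size *n*,
case fraction *K*, and instruments explaining R² of the exposure;
power = Φ(|ln OR|/se − z<sub>1−α/2</sub>). This is the standard
approximation for binary-outcome MR; it is validated by its properties
(power(OR) = power(1/OR); power(1) = α/2; monotone in n, R², |ln OR| and in
K up to ½) rather than against published numbers, which are not part of
the bundled data.

All 95% intervals use z = 1.959964 exactly, which regenerates the bundled
reference CIs at their printed precision.

## Back-derivation of outcome associations

The case-study outcome associations are not shipped as raw GWAS rows;
they are recovered from published per-variant odds ratios:
θ = ln(OR), se(θ) = (ln U − ln L)/(2·1.959964), then γ = θ·β and
se(γ) = se(θ)·|β| (inverting the first-order Wald ratio). Back-derived
values are carried at full double precision, but they inherit the 2–3
significant figures of the published cells; every downstream comparison
budgets for that input rounding (below).

## Comparison tolerances in `reproduce_tables`

Recomputed cells are compared with the bundled references on the log-OR
scale: |Δlog| ≤ max(3% · |log reference|, 0.015) for point estimates and
max(5%, 0.03) for CI bounds. The absolute floors exist because a purely
relative criterion is ill-posed for odds ratios near 1 (log near 0), and
propagating a half-unit rounding of a 2-significant-figure OR such as
0.88 already moves the log by ~0.006; CI bounds additionally compound
rounding through the over-dispersion factor. I² values are compared
within 2 percentage points. Weighted-median CI bounds (bootstrap-based)
and p-value columns (reference-rounding-limited) are reported but not
flagged.

**Known non-derivable cells.** The four brain-cancer MR-Egger reference
cells (and the brain intercept p row) cannot be derived from the bundled
brain per-variant OR/CI cells under any weighting considered, although
the identical procedure reproduces all four liver MR-Egger cells to three
significant figures. The brain per-variant cells are internally
inconsistent: the implied per-variant z-scores contradict the per-variant
p-values published alongside them (e.g. the rs1800562 transferrin cell
5.04 (0.54, 47.4) implies p ≈ 0.16 where p = 0.82 is printed), and the
implied outcome log-odds differ in sign across exposure columns for the
same variant, which is impossible for a shared outcome GWAS under
first-order weighting. The published brain Egger row most plausibly came
from inputs that are not part of the published per-variant tables (for
instance the larger all-variant instrument sets). `reproduce_tables`
therefore flags exactly these cells; all other pooled cells — 8 IVW, 8
weighted-median, 4 liver Egger, the liver intercept, 8 heterogeneity —
pass their tolerances.

## Synthetic-data generator

`simulate_two_sample` draws, in a fixed order for bit-reproducibility:
EAFs uniform on `eaf_range` (default (0.1, 0.9)); true betas with random
signs and half-normal magnitudes scaled so Σ 2·EAF(1−EAF)·β² equals
`total_r2`; exposure estimates β̂ ~ N(β, [2·EAF(1−EAF)·n₁]^(−1/2));
pleiotropic effects α ~ N(μ, σ); outcome truths γ = θβ + sign(β)·α; and
outcome estimates γ̂ ~ N(γ, [2·EAF(1−EAF)·n₂·K(1−K)]^(−1/2)).

Two modelling choices deserve note:

* **Directional pleiotropy is applied in the exposure-increasing allele
  orientation** (the sign(β) factor). Directional pleiotropy is only a
  meaningful concept relative to a consistent orientation; since the
  generator randomizes allele coding signs, adding a fixed-mean α in the
  raw coding would cancel, on average, after MR-Egger's β > 0
  orientation, and no estimator could ever detect it. With the chosen
  convention the Egger intercept is a consistent estimator of μ, which
  the recovery tests verify (mean intercept 0.05 ± 0.01 at μ = 0.05 over
  500 replicates).
* **InSIDE violation** is implemented by reordering the drawn α values to
  rank-correlate with |β| (target Spearman ≈ 0.9). This preserves the
  marginal pleiotropy distribution while inducing the
  strength–pleiotropy dependence that biases the Egger slope; the tests
  check the bias directionally only.

`ukb_scenario("liver"|"brain"|"overall")` returns configurations matching
the case-study outcome cohort: n₂ = 367,643 with 324, 810 or 75,037
cases, n₁ = 48,972, three instruments, R² = 0.034. Under the liver
scenario the generated SEs imply <50% power at OR 1.5 per SD, mirroring
the low-power caveat appropriate for rare site-specific cancers.

What the generator does **not** emulate: linkage disequilibrium between
instruments (the case-study instruments are stated independent,
r² < 0.01), winner's-curse in instrument discovery, individual-level
covariate structure (population stratification, relatedness), allele
miscoding or strand errors, and the joint EAF–effect-size distribution of
real iron loci (the bundled tables, not the generator, carry the real
instruments). Passing recovery tests therefore demonstrate correctness of
the estimators under the stated sampling model — not robustness to those
real-data complications.

### Problem sizes used in the validation suite

Estimator-recovery checks use L = 30 variants with n₁ = n₂ = 200,000,
K = 0.5 and R² = 0.1 (instrument F-statistics ≈ 700, so weak-instrument
dilution is negligible at the tested tolerance), 500 replicates for bias
checks and 1,000 replicates for the type-I-error check. The type-I check
uses fixed-effects IVW at θ = 0 with L = 3: that is the correctly
specified test under homogeneity, whereas the random-effects floor
max(1, √(Q/2)) is deliberately conservative at small L and does not
calibrate to the nominal level. Oracle-equivalence checks run 100 random
3–10-variant sets against plain-loop reimplementations at 10⁻¹⁰ relative
tolerance.

## Numerical and degenerate-input conventions

* p-values that underflow double precision when parsed (e.g. 8.4e-610 in
  the transferrin table) are clamped to 5e-324, the smallest positive
  float, preserving ordering for threshold selection.
* Zero exposure beta, zero-width CIs, non-positive SEs, duplicate
  (variant, trait) rows, and allele pairs incompatible under both strand
  readings are hard validation errors naming the offending variant/row.
* Palindromic (A/T, C/G) variants default to the EAF policy with window
  0.08: aligned by frequency side only when both EAFs are outside
  [0.42, 0.58], else excluded; `strict` and `drop` policies are available.
* Instrument selection ties (equal p) break by smaller SE, then
  lexicographic variant ID. Without a user-supplied r² matrix, variants
  are assumed independent and a warning is logged; no LD is computed from
  reference panels.
* Estimator minimums: IVW ≥ 1 variant (random effects falls back to fixed
  with a warning at L = 1), Q and leave-one-out ≥ 2, weighted median and
  MR-Egger ≥ 3. In sensitivity reruns an infeasible method yields a
  marked-missing entry, not an error.

## Known limitations

* The multiplicative random-effects and normal-quantile Egger conventions
  were selected to match the bundled reference tables; other software
  (additive random effects, t-quantiles) will differ, legitimately, on
  other data.
* The weighted-median SE depends on the bootstrap seed (point estimate
  does not); seed-to-seed variation of the SE is below 5% at the default
  10,000 replicates on the bundled data.
* No MR-PRESSO, mode-based, multivariable or contamination-mixture
  estimators, and no funnel plots or Rücker model selection; the scope is
  the estimator suite above.
* The power formula is an approximation that ignores instrument
  uncertainty and rare-outcome non-collapsibility.
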