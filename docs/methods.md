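# Methods

This note records the statistical model the package implements, the
numerical choices behind it, what the synthetic generator does and does not
emulate, and the known limitations.

## Model

### Uncentered PLS1 (NIPALS)

Given `X` (n subjects × p percentage variables) and a binary response
`y ∈ {0,1}ⁿ`, components a = 1..A are extracted by NIPALS:

    w_a ∝ X_{a-1}' y_{a-1},  ‖w_a‖ = 1
    t_a = X_{a-1} w_a
    p_a = X_{a-1}' t_a / (t_a' t_a),   q_a = y_{a-1}' t_a / (t_a' t_a)
    X_a = X_{a-1} − t_a p_a',          y_a = y_{a-1} − t_a q_a

with `X_0 = X`, `y_0 = y` (no centering by default). The composite
coefficient vector is `b = W (P'W)⁻¹ q`, so in-sample predictions satisfy
`X b = T q` exactly (asserted to 1e-10 in tests). With a univariate
response the inner weight iteration is stationary after one pass; the
tolerance (1e-12 on the weight change, 500-iteration cap) is retained as a
guard.

**No preprocessing, by design.** All variables share the percentage scale;
autoscaling would give noise variables the same magnitude as discriminative
ones and the package deliberately does not offer it. Centering is off by
default; consequently all sums of squares — including the explained-variance
ledger — are taken about the origin, and LV1 aligns with the vector of
variable means (its share of the X-block sum of squares exceeds 90% for
realistic baselines). A `center=True` flag exists chiefly so the fit can be
cross-checked against conventional PLS implementations (scikit-learn's
`PLSRegression` agrees to 1e-8 in the tests).

**Sign convention.** NIPALS components are sign-indeterminate; each
component is flipped so its largest-magnitude weight entry is positive,
making fits bitwise reproducible.

**Explained variance.** Deflation removes rank-one pieces whose sums of
squares are exactly `‖t_a‖²‖p_a‖²` (X block) and `q_a²‖t_a‖²` (y block);
partial percentages are these over the total block sum of squares
(about the origin when uncentered, about the mean otherwise), and totals
are running sums. Residual sums of squares never increase.

**Degenerate directions.** A zero-norm weight direction (e.g. an all-zero
residual after the response is perfectly explained) raises an error from
`fit_pls`; the component-count selector treats it as a natural stopping
point and caps A instead.

### Choosing the number of latent variables

Two criteria are provided; neither is a substitute for substantive choice,
and the CLI accepts explicit counts (presets pin 3 and 4 components for the
two published designs):

- `explained_variance_knee` (default for "auto"): keep the components
  before the first one contributing fewer than 5 percentage points of
  y-block variance (never fewer than one). On the published second model's
  partials (38.1, 26.2, 16.9, 3.4) this keeps 3 — the study itself kept 4;
  the rule is a convenience, not a reproduction claim.
- `loo_cv`: minimize leave-one-out squared prediction error, preferring the
  smallest count within numerical tolerance of the minimum.

### VIP selection

`VIP_j = sqrt( p · Σ_a SSY_a w_ja² / Σ_a SSY_a )` with per-component
response sums of squares `SSY_a = q_a²‖t_a‖²` (weights are unit-norm, so no
renormalization is needed). The identity `Σ_j VIP_j² = p` holds exactly and
is asserted for every fitted model. Selection is strict (`VIP > threshold`,
default 1.0), preserving column order; the two-stage workflow refits on the
selected columns with an independently chosen component count.

### Class modeling

Normal densities `N(μ_k, σ_k)` are fitted to the calculated responses of
each class (sample mean, n−1 SD; ≥3 subjects per class, zero variance is an
error). Shapiro–Wilk p-values are attached; values at or below 0.10 raise a
warning but do not block the fit — normality is the method's working
assumption and the p-values are its evidence trail. The test choice is this
package's (the convention in small-sample practice); only the 0.10 level is
inherited from the workflow being modeled.

With the null hypothesis "the sample belongs to class 0" and class 1 lying
above class 0:

    α(t) = P(N(μ₀,σ₀) > t),   β(t) = P(N(μ₁,σ₁) < t)

(mirrored when class 1 lies below). The risk curve sweeps a uniform grid
over `[min μ − 4·max σ, max μ + 4·max σ]` (default 2001 points). The
equal-error threshold is closed-form, `t* = (μ₀σ₁ + μ₁σ₀)/(σ₀+σ₁)`, at
which both standardized distances equal `|μ₁−μ₀|/(σ₀+σ₁)`; the grid root of
`|α−β|` agrees to grid resolution (tested). Integer-percent rounding is
applied only in reports; raw probabilities are carried everywhere else.
Samples at exactly the threshold are assigned to class 1 (arbitrary, fixed,
documented). `signed_sensitivity` preserves the orientation sign
(Φ((μ₁−μ₀)/(σ₀+σ₁))·100) so that null simulations average near 50% rather
than folding above it.

**In-sample vs leave-one-out responses.** Densities are fitted on in-sample
calculated responses by default, exactly as the classical workflow does.
This is optimistic when p ≫ n: simulations at the package's default
dimensions (350 variables, 36–50 subjects) give in-sample equal-error
sensitivities of 96–100% *even with no planted effect*. The
`response_mode="loo"` extension refits the entire fit–select–refit workflow
once per held-out subject and models the held-out responses instead; under
it, null-effect sensitivity is centred near 50% and a 3-SD effect gives
~100%. Generalization claims in the test suite use the LOO mode; the
default remains in-sample for fidelity to the modeled workflow.

### Score geometry

Rotating the (LV_a, LV_b) score plane counterclockwise by θ and thresholding
the first rotated coordinate is a one-parameter family of linear separators
within the plane. The search scans θ ∈ [0°, 180°) (a vertical line is
invariant under a half turn with sides swapped) at a configurable step
(default 0.5°) and returns the angle maximizing the margin — the gap
between class extremes on the rotated first coordinate — with the
separating value at the gap midpoint. Published figures of this kind quote
specific angles (25°, 49°); those are data-dependent outcomes, not
constants of the method, and cannot be reproduced without the original
cohort.

### Univariate screens

Mann–Whitney U, two-sided, exact null distribution when n₀+n₁ ≤ 12 without
ties (scipy's exact method; validated against full enumeration in tests),
midrank normal approximation with tie and continuity corrections otherwise.
**No multiple-testing correction is applied anywhere** — the modeled
workflow reports raw p < 0.05 across the full panel and the package
preserves that choice; callers wanting FDR control must apply it
themselves. The selection × significance partition counts the variables the
unnormalized PLS misses for scale ("numerical effect") reasons. The
loading–p association uses the stage-2 composite regression coefficients by
default ("loading" is ambiguous in this context; first-component weights
and X-loadings are available via a switch) and Spearman rank correlation.
Note one subtlety established during development: when the screen is
computed on the *same* labels the selection used, selection bias alone
induces a negative |coefficient|–p correlation even for a null effect; the
package's null test therefore permutes the labels seen by the screen.

The CD4 slope rule is ordinary least squares of count on time with the
classical t-test against zero slope at α = 0.05 (the minimal reading of
"linear regression analysis"; the exact test and level used originally are
unstated). "Case" requires a significantly *negative* slope; significantly
positive slopes are controls.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
distribution of immunophenotypes (none was available):

    x_ij = b_j + s_j·( √f·g_j·F_{i,k(j)} + √(1−f)·ε_ij ) + δ·s_j·d_j·y_i

- `b_j ~ U(10, 70)` percent: baselines far from zero so the uncentered LV1
  regime (>90% of X on LV1) holds;
- `s_j ~ U(1, 6)` percent: within-class SD;
- each variable belongs to one of `n_latent_factors = 3` blocks with
  shared-variance fraction `f = 0.4` and random sign `g_j` — a coarse stand-
  in for the parent/child correlation of gated subsets;
- `n_informative = 30` variables receive a class shift of `effect_size`
  (default 1.5) within-class SDs with random direction `d_j`;
- values are clipped to [0, 100]; the clip fraction is monitored and a
  warning is raised above 10% (defaults clip <0.1%).

Default sizes are 22 vs 14 subjects (the case–control design) with a 36 vs
14 preset (the patients-vs-healthy design). Where the emulated study fixed
a quantity (panel width 350, the cohort sizes, the −66 cells/µL/yr median
case slope for trajectories), the defaults use it; the remaining ranges are
this package's choices of a realistic regime, fixed once. One seed fans out
into named substreams (baselines, structure, factors, noise, shifts) so
changing one block's parameters leaves the others' draws intact.

**What a green simulation test establishes** — that the pipeline recovers
planted Gaussian mean-shifts of stated size under block correlation and a
dominant offset — **and what it does not**: real subset frequencies are
compositional (parent/child sum constraints), skewed, and heteroscedastic;
none of that is modeled, so recovery rates here do not predict performance
on real panels.

## Numerical choices

- NIPALS weight-change tolerance 1e-12, max 500 iterations; weight norms
  below ~1e-300 raise a degeneracy error.
- Ledger identities asserted at 1e-9; oracle equivalences at 1e-8.
- Risk-curve grid 2001 points by default (the published-density check uses
  finer grids where resolution matters).
- Rotation search step 0.5°; ties in the margin resolved toward the
  smaller angle (first maximum wins).
- VIP threshold comparison is strict (`>`), so a score exactly 1.0 is not
  selected.
- CSV round-trips use 17-significant-digit formatting and pandas
  round-trip float parsing, making write→read exact.

## Limitations

- The in-sample operating point is an optimistic estimate when p ≫ n (see
  above); the LOO mode is the honest alternative but changes what is being
  estimated (the workflow's generalization, not its in-sample description).
- Only univariate-response PLS is implemented; no multi-class, kernel, or
  sparse variants.
- The equal-error point assumes the two normal densities cross between the
  class means; grossly unequal variances with nested densities are outside
  the intended regime (the normality warnings would fire long before).
- The generator's clipping slightly attenuates planted effects near the
  [0, 100] bounds; monitored, negligible at defaults.
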