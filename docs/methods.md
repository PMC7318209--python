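# Methods

## Model

Zone yield *y* (t/ha) and log nutrient concentration *x* (log mg/L) are
modelled through a latent bivariate normal Z = (Y, X) ~ N₂(μ, C), with the
yield coordinate censored from above by a bounded-linear boundary
Λ(x) = min(β0 + β1·x, β2) and observed with Gaussian error of SD σe.  The
conditional observed-yield density is the convolution of the censored
conditional of Y|X=x (continuous part below Λ plus an atom of mass
1 − Φ((Λ−μ_c)/σ_c) at Λ) with N(0, σe²); it has the closed form given in the
README and is evaluated entirely in log space (`log_ndtr`, `logaddexp`) so
deep-tail observations underflow gracefully.  For σe = 0 the atom is not
smeared and the density is returned for the continuous part only, with zero
density above the boundary.

The likelihood is the **joint** density f(y, x) = f_b(y|x)·N(x; μ_x, σ_x²),
treating zones as independent.  The joint form is what makes μ_x and σ_x
estimable and gives the parameter counts used in the AIC competition
(8 for the boundary model, 5 for the plain bivariate normal, 6 for the
constant-censor variant; σe is never counted because it is fixed upstream).
A conditional-only likelihood — dropping the marginal factor — is available
through `negative_log_likelihood(..., conditional=True)` for sensitivity
checks; it is not used for fitting because μ_x, σ_x are then unidentifiable.

Assumptions worth stating: x is error-free; zones are treated as independent
in the likelihood even though real (and synthetic) yields are spatially
correlated, so reported SEs are plug-in asymptotics, not design-based; the
boundary is an upper censor only; a meaningful boundary needs β1 > 0, which
is enforced at interpretation (x_crit) rather than during optimization.

## Key parameters

| parameter | meaning | default | why |
|---|---|---|---|
| σe (t/ha) | yield observation-error SD, fixed during fits | variogram nugget√ | zone-mean support leaves little besides measurement error at zero lag |
| transform threshold | skewness above which concentrations are logged | 1.0 | matches the descriptive rule used for these data |
| fence factor | bagplot fence = bag scaled by this | 3 | classical bagplot default |
| selection threshold | minimum Akaike weight to adopt the boundary | 0.5 | "more probable than all alternatives together" |
| MC draws | β draws for x_crit uncertainty | 500,000 | published choice; tests use 20,000–100,000 |
| HDI mass | highest-density interval coverage | 0.95 | conventional |
| index bands | P: 10/16/26/46/71 mg/L; K: 60/120/180/240/400; Mg: 25/50/100/175/250 | RB209 advisory bands | user-overridable; provenance recorded in every report |

## Fitting

SDs are optimized as logs and ρ as arctanh, making the search unconstrained.
Starts: latent parameters from closed-form moments (σe² subtracted from the
yield variance, floored at 10⁻⁶); boundary candidates deliberately include
strongly sloped lines — the two-point upper slope, a line through the 0.95
yield quantiles of the lower x-bins, and steep boundaries hinged at interior
x-quantiles — because the likelihood has a *flat-censor local optimum*
(β1 → 0 mimicking MVN_c) that captures naive starts.  Candidates are
screened with a short simplex run; the two best are optimized fully
(Nelder–Mead then L-BFGS-B polish — the surface has kink-induced curvature
where data cross the boundary knot), a second pass re-optimizes with
per-parameter scaling from numerical curvature, and jittered restarts
(default 8; simulation-heavy tests use 2 as a problem-size choice) guard
against residual multimodality.

## Uncertainty

The covariance of the estimates is the inverse numerical Hessian of ℓ at the
optimum in the original parameterization.  Two numerical facts shape the
implementation: the log-likelihood is only piecewise smooth (micro-kinks as
data points cross the knot), and the information matrix is near-singular
along the β0–β1 trade-off.  A pointwise central-difference Hessian is
therefore unstable exactly where it matters; it is used as an initializer
and refined by an iterated least-squares quadratic fit of ℓ over a cloud of
points drawn to match the current covariance estimate (three iterations,
300 points, deterministic seed).  This reproduces both the large-sample
Fisher information and the empirical sampling SD of the boundary parameters
in simulation (3-SE recovery coverage ≈ 95%), where the raw difference
quotient gave non-positive-definite results or SEs a factor ~2 small.
`finite_difference_hessian` remains available directly.

x_crit draws with β1 ≤ 0 are discarded and their fraction reported; if it
exceeds 0.5 the slope sign is judged unstable and inference is refused.  The
95% HDI is the shortest window over the sorted draws; it is computed on the
log scale and exponentiated endpoint-wise by default (a monotone transform
preserves the log-scale HDI, and published intervals are asymmetric in mg/L,
consistent with that reading), with `hdi_scale="mgL"` to compute it directly
on concentrations.

## Preprocessing

Halfspace depth is exact (sorted-angle construction, O(n log n) per point);
above 20,000 points a random subsample defines the bag and fence and all
points are tested against the fence.  The bag is the outermost depth contour
still holding ≥ n/2 points, shrunk about the Tukey median by bisection until
it covers exactly half — an interpolation between adjacent depth contours
that commutes with affine maps, so flagging is affine-invariant.  One pass
is nearly idempotent: in null simulations (n = 1000) a second pass re-flags
at most one borderline point, in ~12% of seeds, because the fence shrinks
slightly after removal.

The empirical variogram is Matheron's, pooled over the dataset (farm means
not removed by default; `demean_by_farm` available).  Equal-width lag bins
run to min(half the maximum inter-point distance, 20× the median
nearest-neighbour distance) — the cap matters for clustered farm layouts,
where kilometre-wide bins would bury the short-range behaviour that
identifies the nugget — and bins with < 30 pairs are dropped.  Spherical and
exponential models are fitted by WLS with weights N/h²; the better objective
wins; a negative nugget is clamped to zero with a warning.  The pipeline
additionally caps σe at 0.8×SD(yield): a nugget rivalling the total yield
variance would make the latent yield variance unidentifiable and indicates a
degenerate input rather than measurement error.

## Synthetic data

The generator emulates the structure the analysis assumes: 150–250 farms of
~27 zones on jittered 150 m grids; latent (Y, X) with the default truth
β = (−21.05, 10.15, 13.64), μ_y = 12, μ_x = 4.0, σ_y = 2.5, σ_x = 0.5,
ρ = 0.3, σe = 0.5 t/ha — yields ≈ 4–17 t/ha, concentrations lognormal (raw
skew > 1, log skew < 1), censoring fraction ≈ 0.29.  With spatial structure
on (the default), the latent pair is built from farm-block Gaussian
processes (Cholesky per farm, farms independent) with range 4000 m — far
above the zone spacing, so zone yields are smooth at short range and the
variogram nugget of observed yield identifies σe², exactly the approximation
the fitting procedure relies on; farms sit 5000 m apart so pooled short-lag
bins are purely within-farm.  An extra structured yield error (partial sill
0.5, same range) plus iid N(0, σe²) noise is added; gross outliers displace
points by 6 marginal SDs in a random direction.  `spatial=None` yields the
exact iid model, used wherever a test needs data from the model itself.

What the generator does **not** emulate: combine-harvester point data and
its cleaning, real soil-survey zone geometry, pH/depth dependence of the
boundary (pH and depth are independent decorations), non-Gaussian latent
tails, and cross-farm spatial continuity.  Passing tests therefore certify
the estimation machinery under the model's own assumptions — not robustness
to the full messiness of commercial yield maps.

## Degenerate inputs and tie-breaks

Collinear point sets are rejected by the bagplot with a pointer to
univariate methods; constant yield fields return an all-zero variogram with
zero nugget; an exact AIC tie involving the boundary model fails the
"strictly smallest" selection rule and is logged; empty subsets warn and the
pipeline's record floor (default 50) refuses to fit.  Pipeline stage
failures are caught per stage and recorded in the report, which is always
emitted.

## Problem sizes in tests

Simulation tests run at the sizes stated in their docstrings — parameter
recovery at n ≈ 5000 over 100 seeds, model competition at n ≈ 2000 over
100 seeds per arm, nugget recovery at n = 2000 over 200 seeds, end-to-end
runs at ~1600 zones — with 2 jittered restarts and 20,000–100,000 MC draws,
the package's own choice of desk-scale study conditions.

## Known limitations

Plug-in SEs ignore spatial correlation, so interval coverage on strongly
correlated data is approximate (visible as occasional non-covering HDIs in
the end-to-end runs).  Selecting a censor level is a
parameter-on-the-boundary problem, so the AIC competition's null behaviour
is not chi-square: on uncensored data the fitted boundary can partly explain
the most extreme upper points through the censoring atom, and the acceptance
suite measures the boundary model being (wrongly) selected in ~17% of
uncensored simulations at n ≈ 2000 — the w ≥ 0.5 rule dampens but does not
remove this; treat single-dataset boundary selections near the threshold
with caution, and note that outlier trimming makes the effect stronger, not
weaker, by sharpening the upper edge of the scatter.  The variogram nugget inherits any genuinely iid
zone-scale yield variance, which inflates σe beyond pure measurement error.
Only the bounded-linear boundary shape is implemented.  Model selection uses
AIC weights alone; no small-sample correction (AICc) is applied.
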