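# Methods

## The modelling problem

A larch crown is sampled whorl by whorl: each observation is a needle
cluster with a vertical coordinate RDINC ∈ (0, 1] (relative depth into the
crown; 0 = apex) and a calendar coordinate DOY, with development time
D = DOY − 120 counted from budburst. The response is leaf mass per area,
LMA = WD/LA (g/m²); the companion trait is leaf dry matter content,
LDMC = WD/WF (g/g). LMA declines with crown depth (shaded lower foliage is
thinner) and follows a unimodal seasonal course (build-up of mesophyll and
cell-wall material, then senescence), so a useful predictive model must be
bivariate in RDINC and D.

Note on conventions: some sources print LDMC as WF/WD; the package uses the
standard WD/WF (values in (0, 1), dimensionally a dry:fresh mass fraction)
and exposes `ldmc_formula="as_printed"` in `compute_traits` for the
reciprocal convention.

## The model catalogue

Thirteen forms are implemented (`model_library`). Models 1–7 are univariate:
linear / exponential / quadratic / power shapes in RDINC (1–4), a quadratic
in D (5), and linear / power shapes in LDMC (6–7; the exponential variant
declared in some sources is available as `"7exp"`). Models 8–13 arise from
the *parameter-prediction* (reparameterization) method: a parent model's
coefficients are replaced by linear or polynomial functions of the second
covariate. The flagship is Model 13,

    LMA = (m0·RDINC + m1) + (m2·RDINC + m3)·D + m4·D²,

a RDINC-linear level with a RDINC-modulated linear D term and a quadratic
D term. Published coefficient sets for all 13 models ship as a versioned
JSON fixture, with the printed (rounded) digits preserved.

Internally, coefficients are stored in canonical order; for the D-quadratic
Model 5 canonical order is (quadratic, linear, constant), with
`coefficients_printed` exposing the intercept-first layout used in printed
tables.

### Fitting

Forms linear in their parameters (1, 3, 5, 6, 8, 9, 11, 13) are solved
exactly by ordinary least squares on the basis expansion (`numpy.lstsq`;
singular designs are rejected). The genuinely nonlinear forms (2, 4, 7, 10,
12) use Levenberg–Marquardt (`scipy.optimize.least_squares`, ftol = xtol =
gtol = 1e−14) from deterministic starts obtained by log-linearisation: the
exponential/power shapes start from an OLS fit of log LMA on the (possibly
logged) predictor; the bivariate power forms (10, 12) first estimate the
LDMC exponent from the pooled log–log slope and then solve the remaining
coefficients by conditional OLS. With these starts the noiseless-limit
duality fit(evaluate(m)) = m holds to better than 1e−8 relative error for
every form (property-tested).

## Assessment statistics (`metrics`)

R² = 1 − SSE/SST, R²ₐ = 1 − (1 − R²)(n − 1)/(n − p), RMSE = √(SSE/(n − p)),
ME and MAE with divisor n, and the fit index FI = 1 − SSE/SST on a
validation set (identical formula to R², different data). The mixed
divisors (n − p for RMSE, n for ME/MAE) are intentional and follow common
forestry practice. AIC is the least-squares form n·ln(SSE/n) + 2p; absolute
AIC is convention-dependent (an additive constant), so only AIC differences
between models fitted to the same response are meaningful, and model
selection uses AIC only as the final tie-break after R²ₐ and RMSE. Under
Gaussian residuals MAE/RMSE (both divisor n) → √(2/π) ≈ 0.798, a useful
consistency check on validation tables.

## The pipeline (`workflow`)

1. **Split** — seeded random 75/25; the fitting set takes ⌈0.75 n⌉ records
   (779 → 585/194). An optional stratify-by-tree flag splits within trees;
   plain random is the default since the original design is unstated.
2. **Discretize** — half-open bins, right-closed at the domain top: RDINC
   width 0.1 (ten raw bins over (0, 1]; bins with n < 10 merge into the
   nearest populated neighbour, logged — on realistic data this typically
   leaves nine), DOY width 15 anchored at 150 (the biweekly grid 150–240
   gives exactly six groups, the top bin [225, 240] closed).
3. **Parameter trends** — the parent model is refitted per bin and each
   parameter regressed on the bin midpoint with polynomials of degree 1–3,
   ranked by adjusted R². This is diagnostic only: the bivariate forms are
   fixed catalogue members (cubic D appears in Model 11, quadratic in
   12–13), not auto-derived.
4. **Selection** — highest R²ₐ, ties by lower RMSE, then lower AIC.
5. **Validation** — ME / MAE / FI for every candidate on the held-out set.

Pipeline runs are deterministic at fixed seed and serialize with full
provenance (seed, config hash, sizes, diagnostics, package version).

## Group statistics (`group_stats`)

**SMA regression** (standardized major axis, the standard symmetric
line-fit for trait–trait allometry): slope = sign(r)·SD(y)/SD(x) through
the centroid; 95% CI via the B-statistic construction
b·(√(B+1) ± √B), B = F₀.₉₅(1, n−2)(1−r²)/(n−2). Axes are raw by default
(a log–log option exists) since trait coupling here is analysed on linear
axes. |SMA slope| ≥ |OLS slope| always, with equality only at |r| = 1.

**Common-slope test**: at a candidate slope b the residual axis y − bx and
fitted axis y + bx are uncorrelated within a group exactly when b is that
group's SMA slope. The statistic Σᵢ −(nᵢ − 5/2)·ln(1 − rᵢ(b)²), minimised
over b (bounded scalar search on a log-magnitude bracket spanning the
group slopes), is χ²(k−1) under a shared slope; the Bartlett factor
nᵢ − 5/2 is the small-sample correction for a correlation likelihood
ratio. Null simulation (1000 replicates, k = 3, n = 30) gives a KS distance
of 0.015 from χ²₂ and a 4.6% rejection rate at nominal 5%. The statistic is
invariant to group relabelling and to affine rescaling applied jointly to
all groups.

**Two-way ANOVA**: LMA against sampling period × crown layer with
interaction, Type III sums of squares with sum-to-zero contrasts
(statsmodels OLS + `anova_lm`), appropriate for unbalanced whorl data;
sequential (Type I) available by flag. The "period" factor is the six
biweekly DOY bins, not the three named growth phases — a 6-level factor is
what a df = 5 main effect implies — though the three-phase labels are also
available as a grouping column.

## The synthetic generator (`synthetic_data`)

The generator emulates the *statistical* structure of a whorl-sampling
campaign, not its biophysics (no light or water-potential mechanism):

- **Covariates.** RDINC ~ truncated normal, mean 0.52, SD 0.26, support
  [0.08, 0.99]; DOY on the biweekly grid {150, …, 240}. Default per-date
  weights are a discretized Gaussian moment-matched to the study-scale DOY
  mean 199.15 and SD 26.88 (field campaigns rarely sample every date
  equally; a uniform grid would have mean 195 and SD 30). A deterministic
  `grid` mode (plots × trees × whorls × clusters × dates) is also provided.
- **LMA.** The published Model 13 surface plus N(0, σ²) noise, σ = 10.25
  g/m² by default (the residual scale of the published fit), floored at 5
  g/m²; floor events are counted and logged (they bias moments if
  frequent). Expected pooled mean ≈ 68.2 g/m² and SD ≈ 17.4 g/m² at the
  defaults, close to the study-scale 67.75 and 18.12.
- **LDMC.** Obtained by inverting the linear LMA–LDMC relation
  (slope 156.76, intercept 15.56) applied to the *noiseless* surface, plus
  N(0, 0.04²) noise, clipped to [0.05, 0.65], with per-layer slope
  multipliers UC/MC/LC = 1.2/1.0/0.8 so the SMA heterogeneity analysis has
  real structure to find. Coupling to the mean surface rather than the
  noisy LMA realisation is deliberate: otherwise LDMC would inherit the
  LMA residual and LDMC-based models would spuriously dominate the true
  generating surface. With this choice r(LMA, LDMC) ≈ 0.6–0.7 and the
  pipeline selects the generating form.
- **Determinism.** One seeded generator per dataset; covariates are drawn
  before noise, so noisy and noiseless runs at the same seed share
  covariates; identical seed + config give byte-identical CSV.

What passing tests on this generator do *not* show: robustness to real
crowns' within-tree autocorrelation, measurement error in LA, non-Gaussian
residuals, or true late-season (post-DOY-240) behaviour — the default
campaign ends in August, so the late growth phase is structurally empty
(summary tables flag those cells with n = 0 rather than dropping them,
mirroring the ambiguity of late-season bookkeeping in such campaigns).

## Problem sizes and numerical choices

Simulation-based checks use study-scale sizes chosen to keep the full suite
fast while statistically meaningful: parameter-recovery at n = 50,000 (one
fit) and 120 replicates at n = 585 for coverage; 1000 null replicates for
the common-slope χ² calibration; 600 null replicates (±3 binomial SE band)
for the ANOVA type-I rate; n = 10⁵ for law-of-large-numbers and MAE/RMSE
asymptotics. Degenerate inputs are rejected with named fields (zero
variance, empty design cells, singular designs, out-of-domain covariates);
ties in bin-merging resolve toward the lower bin; the power-law RDINC form
is rejected at RDINC = 0 where it is singular.

## Known limitations

- Absolute AIC values are not comparable across software conventions; only
  differences are contract-stable.
- The crown-layer boundaries (RDINC tertiles) are a convention, exposed as
  configurable cut points.
- No bootstrap coefficient intervals, no AICc, no post-hoc multiple
  comparisons; the 75/25 split is the only validation scheme.
- The generator's LDMC coupling is linear per layer; curvature in trait
  coupling is not emulated.
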