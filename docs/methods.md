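# Methods

## Model and assumptions

The package implements a phenomenological model of tumor-cell migration:
classical anisotropic diffusion, but posed in a fractally rescaled
space-time frame. Physical coordinates (x₁, x₂, x₃) in mm and time t in
days map to fractal coordinates rᵢ = sign(xᵢ)·|xᵢ|^βᵢ and the internal
clock t̂ = t^α. In that frame the positional probability density p(r⃗, t̂)
obeys the constant-coefficient diffusion equation ∂p/∂t̂ = Σᵢ Dᵢᵢ ∂²p/∂rᵢ²
with a diagonal tensor D and point-source (Dirac) initial data, whose Green
function is the anisotropic Gaussian

p(r⃗, t̂) = det(D)^{-1/2} (4π t̂)^{-3/2} exp(−Q/4t̂),  Q = Σᵢ rᵢ²/Dᵢᵢ.

Assumptions worth making explicit:

- **Probability lives in the fractal frame.** The density integrates to 1
  over r⃗ ∈ ℝ³, not over physical x⃗; the Jacobian between frames is not
  part of the model. Physical-frame values are exposed only as point
  evaluations of p at transformed coordinates.
- **The power law is extended to negative coordinates as an odd function**
  (sign(x)·|x|^β). This is a modelling choice: it keeps the frame
  symmetric about the origin so that a point-source solution satisfies
  p(r) = p(−r), which any reasonable reading of the model requires. Only
  positive coordinates appear in the original simulation settings.
- **RTOP is a density, not a probability.** The return-to-origin statistic
  RTOP(t) = p(0, t̂) = det(D)^{-1/2}(4π t^α)^{-3/2} diverges as t → 0 and
  can exceed 1. It is deliberately not clamped: clamping would destroy the
  log–log linearity (slope −3α/2) that the parameter fit inverts.
- **Units are model units.** Diffusion entries are fractal-length² per
  fractal-time (mm^2β per day^α read numerically); the library performs no
  automatic unit conversion inside the model core. The Stokes–Einstein
  helper converts SI m²/s to mm²/day by the factor 8.64 × 10¹⁰ and
  documents that the fractal-unit caveat applies downstream.

## Parameters

| Parameter | Meaning | Default | Why |
|---|---|---|---|
| α | time exponent (internal clock) | 0.4 | the value used in the model's published simulation curves |
| βᵢ | space exponents | 0.9 (all axes) | same; stored per-axis because the frame defines them separately |
| Dᵢᵢ | diffusion tensor diagonal, model units | 0.01 (time-course), 10⁻⁶ (surface) | the two simulation settings; no single global default is meaningful |
| λ | CAM copies-per-cell normalization | estimated from data (0.05 in fixtures) | the model gives no value; treated as constant in time |
| T, η, r | temperature, viscosity, particle radius | T = 310.15 K in examples; η, r required | no canonical cell radius exists, so radius is a required input rather than a fabricated default |

Admissible α > 1 (a super-diffusive clock) is not ruled out by the frame
definition; the library accepts any α > 0 and leaves the interpretation to
the user.

## Numerical choices

- **Normalization check**: the Gaussian factorizes over axes, so the triple
  integral is computed as a product of three adaptive 1-D quadratures
  (scipy `quad`, abs/rel tolerance 1e-9), each truncated at 10 standard
  deviations (σᵢ = √(2Dᵢᵢt̂)); the truncated tail is ≈ 1.5 × 10⁻²³ per
  axis, far below the 1e-6 contract.
- **Peak time**: maximizing t̂^{-3/2}·exp(−Q/4t̂) analytically gives
  t̂* = Q/6, hence t* = (Q/6)^{1/α} in days; the time-course grid argmax is
  only used as an independent oracle in tests.
- **Underflow at the surface settings**: with Dᵢᵢ = 10⁻⁶ the density at
  x₁ = 0.5 mm is of order exp(−4500) — positive in exact arithmetic but
  far below float64. `spatial_profile(..., log=True)` returns the analytic
  log-density, which stays finite; the CSV surface carries both `density`
  (which honestly underflows to 0) and `log_density` columns.
- **RTOP fitting**: unweighted ordinary least squares of ln p on ln t
  (scipy `linregress`); exact inversion for noise-free series, and under
  multiplicative lognormal noise the log-scale errors are homoscedastic
  Gaussian, making OLS the natural estimator. α = −2·slope/3; det D from
  the intercept; standard errors propagate linearly (delta method for
  det D).
- **λ estimation**: regression through the origin, λ = Σpc/Σc², because the
  mapping asserts exact proportionality; scale-equivariant and exact on
  noise-free data.
- **Lattice walks**: simple cubic lattice, uniform step probability 1/(2d).
  The Monte-Carlo estimator counts first returns within a finite horizon,
  so it is a lower bound with truncation bias shrinking as the horizon
  grows (the bias is left in and reported with the horizon; no tail
  extrapolation). The RNG is explicitly seeded and the jitted kernel is
  bit-reproducible for a fixed seed and library version.
- **Exact enumeration**: integer path counting with an absorbing origin
  gives the exact first-return distribution as rational numbers
  (`fractions.Fraction`), budget-limited to 24 steps where the state space
  and big-integer counts stay small.
- **Pólya constant**: 1 − 1/u with Watson's integral u evaluated two
  independent ways — the Γ-function product closed form
  u = √6/(32π³)·Γ(1/24)Γ(5/24)Γ(7/24)Γ(11/24), and adaptive triple
  quadrature of (2π)⁻³∫dk/(1 − (cos k₁+cos k₂+cos k₃)/3) over [−π,π]³
  (reduced by symmetry to [0,π]³; the 1/|k|² singularity at the origin is
  integrable and handled by the adaptive scheme). The two agree to ~1e-12.
- **Classical-limit check**: Brownian walker positions at time t are exact
  Normal(0, 2Dt) draws per axis. The chi-square goodness of fit uses exact
  Gaussian cell masses (products of per-axis CDF differences) rather than
  density-times-volume, with an overflow cell for everything outside the
  histogram extent and pooling of cells with expected count < 5.
- **Finite-difference residual tests** use Richardson-extrapolated central
  differences (O(h⁴), h = 5 × 10⁻³) so the oracle's truncation error sits
  well below the 1e-6 contract while remaining independent of the analytic
  derivatives.
- **t = 0 is excluded everywhere**: the initial condition is a point mass,
  not a density, so grids start at 1 day by default and t = 0 raises.

## Synthetic data

`generate_fixtures` emulates the only data the analysis consumes: an RTOP
time series with a paired CAM concentration-ratio series. Times are
log-spaced (natural for a power-law decay), the clean RTOP curve gets
independent multiplicative lognormal noise with median 1 and log-scale
standard deviation σ (default 0.05, i.e. ≈ 5% noise — a realistic assay
coefficient of variation), and the CAM series is the noisy density divided
by λ (default 0.05) with its own independent noise draw. Defaults are 50
points over days 1–1000.

What the generator does *not* emulate: biological heterogeneity between
tumors, time-varying λ, censoring or detection limits, correlated
measurement error between the probability and CAM channels, and any
deviation of real migration from the fractal-Gaussian law itself. Passing
recovery tests therefore demonstrates that the inversion machinery is
correct and calibrated under the model's own assumptions — not that real
CAM measurements follow the model.

## Problem sizes

Monte-Carlo verification uses 10⁵ walks truncated at 10⁴ steps (binomial
standard error ≈ 1.5 × 10⁻³); the Brownian ensemble uses 10⁵ walkers in an
8³ histogram; enumeration oracles run to 12 steps. These sizes give
comfortable statistical margins for every 3-standard-error check while
keeping the full verification run in well under a minute of compute after
JIT warm-up.

## Known limitations

- The fractal-frame normalization means physical-frame probabilities are
  not conserved under the transform; cross-frame comparisons are point
  evaluations only.
- Stokes–Einstein is derived for molecular/colloidal particles; applying
  it to ~10 µm cells is an idealization adopted deliberately, with the
  radius left as a required user input.
- The equality of benign-tumor CAM ratios with the lattice constant is a
  comparison the library exposes, not a derivation: no quantitative
  equation links tissue concentration ratios to the lattice walk beyond
  the proportionality mapping.
- Heavy-tailed (Lévy-stable) propagators, continuous-time random walks
  with waiting-time distributions, tumor growth mechanics, and disordered
  lattices are out of scope.
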