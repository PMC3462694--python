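# selfseed

A simulation and analysis library for a fractal anomalous-diffusion model of
tumor cell migration and "tumor self-seeding" — the tendency of migrating
tumor cells to return to, or remain near, their site of origin.

## Who this is for

Researchers in mathematical oncology and cell-migration biophysics who want
a small, well-tested implementation of the closed-form fractal Gaussian
propagator, the return-to-origin-probability (RTOP) statistic, its mapping
to cell-adhesion-molecule (CAM) expression ratios, and the Stokes–Einstein
coupling between microenvironment viscosity and the diffusion coefficient —
plus the classical lattice-walk machinery (the 3D Pólya constant) that
anchors the self-seeding interpretation.

## The model

Cell positions evolve by ordinary anisotropic diffusion, but in a fractally
rescaled space-time frame

```
r_i = sign(x_i) |x_i|^{β_i},   t̂ = t^α          (α, β_i > 0)
```

so that the positional probability density solves ∂p/∂t̂ = Σᵢ Dᵢᵢ ∂²p/∂rᵢ²
with diagonal diffusion tensor D and a point source at the origin. The
closed-form solution is the anisotropic Gaussian

```
p(r⃗, t̂) = det(D)^{-1/2} (4π t̂)^{-3/2} exp( -Q / 4t̂ ),    Q = Σᵢ rᵢ²/Dᵢᵢ .
```

Three derived quantities drive the analysis:

- **RTOP** — the density at the origin, `RTOP(t) = det(D)^{-1/2} (4π t^α)^{-3/2}`,
  a power law with log–log slope −3α/2. Its decay is the model's signature
  of self-seeding fading as a tumor grows; `fit_rtop_series` inverts a
  measured series back to (α, det D) by log–log least squares.
- **Biphasic curve** — at any fixed off-origin point the density first rises
  then falls, peaking at the closed-form time `t* = (Q/6)^{1/α}`.
- **CAM mapping** — the measurable proxy: `p = λ·c`, where c is the
  tumor-vs-normal CAM concentration ratio and λ a constant normalization
  factor estimated by through-origin least squares.

Two verification engines accompany the model: exact/Monte-Carlo/closed-form
evaluations of the 3D lattice return probability (Pólya's constant
0.340537, via Watson's integral), and a Brownian-walker ensemble that
reproduces the propagator in the classical limit α = β = 1. The
`microenvironment` module converts a medium's viscosity into a diffusion
coefficient through D = k_B·T/(6πηr).

## Worked example

```python
import numpy as np
from selfseed import (ModelConfig, FractalExponents, DiffusionTensor,
                      rtop, peak_time, fit_rtop_series, polya_constant_3d)
from selfseed.cli import generate_fixtures

config = ModelConfig(FractalExponents(alpha=0.4, beta=0.9),
                     DiffusionTensor.isotropic(0.01))   # mm^2β / day^α

print(rtop(10.0, config))                    # 5.638780691750748
print(rtop(100.0, config))                   # 1.4163976709866903
print(peak_time((0.5, 0.5, 0.5), config))    # 781.2499999999998

frame, meta = generate_fixtures(config, sigma=0.05, n_points=50, seed=7)
fit = fit_rtop_series(frame["t_days"], frame["rtop_density"])
print(fit.alpha, fit.alpha_stderr)           # 0.39813460519328175 0.0020757041279961903
print(polya_constant_3d())                   # 0.34053732955099936
```

RTOP falls from 5.64 to 1.42 (densities per unit fractal volume) between
day 10 and day 100 — the predicted fading of self-seeding. The density at
(0.5, 0.5, 0.5) mm peaks at t* ≈ 781 days: growth first, dispersal after.
A noisy synthetic RTOP series (5% lognormal noise, 50 points) fits back to
α = 0.398 ± 0.002, recovering the generating α = 0.4 well within error.
The final line is the probability that a simple symmetric random walk on
the 3D cubic lattice ever returns to its origin — the model's baseline for
self-seeding in a periodic microenvironment.

The same computations are scriptable from a shell:

```
selfseed fig1 --out fig1.csv         # RTOP/density surface, x1 ∈ [0.5, 0.7] mm, t ∈ [1, 1000] d
selfseed fig3 --out fig3.csv         # biphasic time course at (0.5, 0.5, 0.5) mm
selfseed polya                       # 3D return probability, four independent routes
selfseed fixtures --sigma 0.05 --seed 7 --out fix.csv
selfseed fit --input fix.csv
selfseed stokes --radius-m 1e-5 --viscosity-poise 14.1 --viscosity-poise 18.3
```

All outputs are deterministic for a fixed configuration and seed.

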