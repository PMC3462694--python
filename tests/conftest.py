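import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from selfseed import DiffusionTensor, FractalExponents, ModelConfig, propagator_fractal

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def pde_rel_residual(tensor: DiffusionTensor, r, t_hat: float, h: float = 5e-3) -> float:
    """Relative residual of dp/dt_hat - sum_i D_ii d2p/dr_i2 for the closed
    form, via Richardson-extrapolated (O(h^4)) central differences — an
    oracle independent of the analytic derivatives."""
    r = np.asarray(r, dtype=float)

    def p(rr, tt):
        return propagator_fractal(rr, tt, tensor)

    def d_dt(step):
        return (p(r, t_hat + step) - p(r, t_hat - step)) / (2 * step)

    def lap(step):
        total = 0.0
        for d_ii, e in zip(tensor.diagonal, np.eye(3) * step):
            total += d_ii * (p(r + e, t_hat) - 2 * p(r, t_hat) + p(r - e, t_hat)) / step**2
        return total

    dpdt = (4 * d_dt(h / 2) - d_dt(h)) / 3
    laplacian = (4 * lap(h / 2) - lap(h)) / 3
    return abs(dpdt - laplacian) / max(abs(dpdt), abs(laplacian), 1e-300)


@pytest.fixture(scope="session")
def fig3_config() -> ModelConfig:
    """Biphasic-curve simulation parameters: D_ii = 0.01, alpha = 0.4, beta = 0.9."""
    return ModelConfig(FractalExponents(alpha=0.4, beta=0.9), DiffusionTensor.isotropic(0.01))


@pytest.fixture(scope="session")
def fig1_config() -> ModelConfig:
    """RTOP-surface simulation parameters: D_ii = 1e-6, alpha = 0.4, beta = 0.9."""
    return ModelConfig(FractalExponents(alpha=0.4, beta=0.9), DiffusionTensor.isotropic(1e-6))


@pytest.fixture(scope="session")
def classical_config() -> ModelConfig:
    """Identity frame and unit tensor: the standard 3D heat kernel."""
    return ModelConfig(FractalExponents(alpha=1.0, beta=1.0), DiffusionTensor.isotropic(1.0))
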