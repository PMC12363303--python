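import numpy as np
import pytest

from blebmetrics import PhantomSpec, PressureSimSpec, InjectionProtocol


@pytest.fixture
def clean_spec():
    """Noiseless default phantom (1 mm isotropic, 4.5 mL-scale bleb)."""
    return PhantomSpec(noise_sd=0.0, seed=0)


@pytest.fixture
def noisy_spec():
    """High-contrast phantom with 20 HU Gaussian noise."""
    return PhantomSpec(noise_sd=20.0, seed=42)


@pytest.fixture
def protocol_4p5():
    return InjectionProtocol(volume_ml=4.5, flow_rate_ml_min=10.0)


@pytest.fixture
def noiseless_sim(protocol_4p5):
    return PressureSimSpec(protocol=protocol_4p5, baseline_kpa=0.0,
                           A1_kpa=10.0, A2_kpa=5.0, k1_per_s=0.5,
                           k2_per_s=0.05, noise_sd=0.0, rate_hz=10.0,
                           duration_s=180.0, seed=0)


def ellipsoid_surface_quadrature(a: float, b: float, c: float,
                                 n: int = 400) -> float:
    """Independent surface-area oracle: Gauss-Legendre quadrature of the
    first-fundamental-form integral over the ellipsoid parametrisation
    r(theta, phi) = (a sin t cos p, b sin t sin p, c cos t)."""
    xs, ws = np.polynomial.legendre.leggauss(n)
    theta = 0.5 * np.pi * (xs + 1.0)
    wt = ws * np.pi / 2.0
    phi = np.linspace(0.0, 2.0 * np.pi, 2 * n, endpoint=False)
    dphi = 2.0 * np.pi / (2 * n)
    st, ct = np.sin(theta)[:, None], np.cos(theta)[:, None]
    cp, sp = np.cos(phi)[None, :], np.sin(phi)[None, :]
    integrand = st * np.sqrt((b * c * cp) ** 2 * st ** 2
                             + (a * c * sp) ** 2 * st ** 2
                             + (a * b) ** 2 * ct ** 2)
    return float((wt[:, None] * integrand * dphi).sum())
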