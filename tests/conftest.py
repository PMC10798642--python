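"""Shared fixtures: canonical parameter set, session-wide correlation
table, and an independent scipy.quad oracle for the correlation integral."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import j0

from caillefit.model import (BeamModel, CailleParameters, FiniteSizeModel,
                             build_unit_correlation_table)
from caillefit.reduction import DetectorGeometry


@pytest.fixture(scope="session")
def params():
    """Canonical POPC-like stack: eta=0.1, xi=60 Å, d=53 Å."""
    return CailleParameters(eta=0.1, xi=60.0, d=53.0)


@pytest.fixture(scope="session")
def size_model():
    d = 53.0
    return FiniteSizeModel(Lr_mean=3000.0, Lr_sigma=1000.0,
                           Lz_mean=10 * d, Lz_sigma=2 * d, d=d)


@pytest.fixture(scope="session")
def small_size_model():
    """Compact domains for fast fitting tests."""
    d = 53.0
    return FiniteSizeModel(Lr_mean=1200.0, Lr_sigma=400.0,
                           Lz_mean=10 * d, Lz_sigma=2 * d, d=d)


@pytest.fixture(scope="session")
def geometry():
    """Rotating-anode-like geometry; q_z reaches ≈0.52 Å⁻¹, q_par ≈0.41."""
    return DetectorGeometry(distance_L=150.0, pixel_size=0.1,
                            beam_center=(95.0, 150.0), wavelength=1.5418)


@pytest.fixture(scope="session")
def beam():
    return BeamModel(sigma_q=0.002)


@pytest.fixture(scope="session")
def unit_table(size_model):
    """Session unit-scale correlation table, 350 nodes/decade."""
    return build_unit_correlation_table(np.geomspace(1e-5, 1e6, 3850),
                                        n_max=size_model.n_support)


@pytest.fixture(scope="session")
def fixture_image(params, size_model, geometry, beam, unit_table):
    """Painted detector image with specular peaks, 50-count background
    and Poisson noise; shared by the reduction and end-to-end tests."""
    from caillefit.synthetic import FixtureSpec, synthesize_detector_image
    spec = FixtureSpec(caille=params, size=size_model, geometry=geometry,
                       beam=beam,
                       specular_orders={1: 2e5, 2: 6e4, 3: 2e4, 4: 8e3},
                       background=50.0, noise="poisson",
                       diffuse_counts=5000.0, seed=7)
    img, truth = synthesize_detector_image(spec, unit_table=unit_table)
    return img, truth, spec


def quad_oracle_core(n: int, r: float) -> float:
    """Independent evaluation of the unit-scale correlation integral
    I(n, r) with scipy.integrate.quad in the w = sqrt(2x) variable.

    Slow but entirely independent of the package's panel quadrature.
    """
    def f(w):
        x = 0.5 * w * w
        root = np.sqrt(1.0 + x * x)
        p = 1.0 / (x + root)
        return (1.0 - j0(r * w) * p ** (2 * n)) * 2.0 / (w * root)

    # only the n=0 integrand needs the Bessel factor resolved far out
    W = max(np.sqrt(120.0), (80.0 / r if (r > 0 and n == 0) else 0.0))
    val, _ = quad(f, 0.0, W, limit=4000, epsabs=1e-12, epsrel=1e-11)
    return val + np.arcsinh(2.0 / W ** 2)


def quad_oracle_delta_u(n, r, p) -> float:
    """delta_u_n(r) from the quad oracle at physical scale."""
    return 2.0 * p.eta / p.q1 ** 2 * quad_oracle_core(n, r / p.xi)
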