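import numpy as np
import pytest

from sastubes import (CoreShellCylinderParams, GaussianBilayerProfile,
                      MultiShellParams, ScatteringCurve)


@pytest.fixture
def q_coarse():
    """Small log grid spanning the usual reduced-SAXS window."""
    return np.logspace(-3, -0.5, 60)


@pytest.fixture
def simple_curve():
    q = np.linspace(0.01, 0.1, 10)
    return ScatteringCurve(q=q, I=np.arange(1.0, 11.0),
                           sigma=np.full(10, 0.5), label="toy")


@pytest.fixture
def hollow_tube():
    """Thin-walled hollow tube, the published long-cylindrical-shell values."""
    return CoreShellCylinderParams(R=1400.0, s=23.0, rho_core=0.0,
                                   rho_shell=-8.7e-4, rho_solv=0.0,
                                   L=1e5, sigma_R=0.0)


@pytest.fixture
def bilayer_profile():
    return GaussianBilayerProfile(rho_C=-1.0, sigma_C=1.9, rho_H=0.55,
                                  sigma_H=4.3, r_H=11.5)


@pytest.fixture
def five_shell():
    return MultiShellParams(radii=np.array([480.0, 500.0, 510.0, 530.0, 540.0]),
                            rhos=np.array([0.0, -1.0, 0.6, -1.0, 0.6]),
                            L=2000.0, sigma_R=0.0)
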