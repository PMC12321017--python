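"""Synthetic scattering curves with realistic noise.

No measured curves are distributed with this package, so every test and
worked example runs on curves generated here: a composite model evaluated
on a log-spaced grid spanning the usual reduced-SAXS window
(10^-3 - 0.5 1/A, ~3 decades), with multiplicative Gaussian noise plus an
additive floor, and a sigma column equal to the true per-point standard
deviation.  Gaussian (not Poisson) noise matches reduced data, whose error
bars are propagated Gaussian estimates - exactly what the error-weighted
chi-square fit assumes.

``preset`` returns ready-made composite models assembled from published
parameter sets: the two-component nanotube + lamellar-bilayer fit of the
C16-KKFFVLK lipopeptide, a bare long hollow cylinder, the full-wrapping
helical ribbon, and a many-turn cochleate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cochleates import CochleateParams
from .composite import Component, CompositeModel, FlatGaussianBilayerParams
from .curves import ScatteringCurve
from .cylinders import CoreShellCylinderParams
from .ribbons import HelicalRibbonParams
from .structure_factors import CailleParams

__all__ = ["NoiseModel", "make_curve", "preset", "PRESET_NAMES"]


@dataclass
class NoiseModel:
    """Gaussian noise: fractional level ``relative``, additive ``floor``."""

    relative: float = 0.01
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.relative < 0 or self.floor < 0:
            raise ValueError("relative and floor must be >= 0")


def make_curve(model: CompositeModel, qmin: float = 1e-3, qmax: float = 0.5,
               n_points: int = 300, spacing: str = "log",
               noise: NoiseModel | None = None) -> ScatteringCurve:
    """Simulate a measured curve from a composite model.

    ``I_obs = I_model (1 + relative Z) + floor Z'`` with Z, Z' standard
    normal from the seeded generator; the sigma column is the true
    standard deviation ``sqrt((relative I_model)^2 + floor^2)`` (zero
    sigmas are replaced by a machine-epsilon floor so the curve stays a
    valid weighted-fit input).  Deterministic per seed.
    """
    if not qmin < qmax:
        raise ValueError("require qmin < qmax")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if spacing == "log":
        q = np.logspace(np.log10(qmin), np.log10(qmax), n_points)
    elif spacing == "linear":
        q = np.linspace(qmin, qmax, n_points)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    noise = noise or NoiseModel(relative=0.0, floor=0.0)
    I_model = model.evaluate(q).I
    sigma = np.sqrt((noise.relative * I_model) ** 2 + noise.floor ** 2)
    rng = np.random.default_rng(noise.seed)
    z = rng.standard_normal(n_points)
    z2 = rng.standard_normal(n_points)
    I_obs = I_model * (1.0 + noise.relative * z) + noise.floor * z2
    tiny = np.finfo(float).eps * np.maximum(np.abs(I_model), 1.0)
    sigma = np.maximum(sigma, tiny)
    return ScatteringCurve(q=q, I=I_obs, sigma=sigma, label="synthetic curve")


def _preset_kkffvlk_like() -> CompositeModel:
    """Two-component lipopeptide-nanotube fit: flat Gaussian bilayer with a
    Caille lamellar factor plus a long hollow cylinder."""
    bilayer = FlatGaussianBilayerParams(
        t=23.0, dt=1.3, rho_H=6.1e-3, sigma_H=4.3,
        rho_C=-5.96e-3, sigma_C=1.9, D=403.0)
    caille = CailleParams(N=2, d=284.0, eta=0.063, nu=18.3)
    shell = CoreShellCylinderParams(
        R=1400.0, sigma_R=27.0, s=23.0,
        rho_core=1.01e-4, rho_shell=-4.64e-5, rho_solv=1.10e-4, L=6.31e6)
    return CompositeModel(
        components=[Component(0.034, bilayer, caille),
                    Component(0.015, shell)],
        background=2.77, scale=1.0)


def _preset_coreshell_tube() -> CompositeModel:
    """Single long hollow cylinder (core density = solvent density)."""
    shell = CoreShellCylinderParams(
        R=1400.0, sigma_R=27.0, s=23.0,
        rho_core=1.10e-4, rho_shell=-7.60e-4, rho_solv=1.10e-4, L=1e5)
    return CompositeModel(components=[Component(1.0, shell)])


def _preset_ribbon_fullwrap() -> CompositeModel:
    """Helical ribbon at the full-wrapping point (width = pitch)."""
    ribbon = HelicalRibbonParams.from_angle(
        R=200.0, psi_deg=27.0, w=326.0, m=10, rho=1.0,
        pitch_convention="tan2")
    return CompositeModel(components=[Component(1.0, ribbon)])


def _preset_cochleate_demo() -> CompositeModel:
    """Cochleate with layer repeat 2 pi D = 100 A and 8 turns."""
    coch = CochleateParams(D=100.0 / (2 * np.pi), m=8, delta=2000.0,
                           p=0.0, rho=1.0)
    return CompositeModel(components=[Component(1.0, coch)])


_PRESETS = {
    "kkffvlk_like": _preset_kkffvlk_like,
    "coreshell_tube": _preset_coreshell_tube,
    "ribbon_fullwrap": _preset_ribbon_fullwrap,
    "cochleate_demo": _preset_cochleate_demo,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str) -> CompositeModel:
    """Return a named published parameterization as a composite model."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    return factory()
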