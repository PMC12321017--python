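"""Cylindrically symmetric form factors.

Covers the whole nanotube family: the decoupled axial x cross-section
product for long cylinders, uniform and core-shell cylinders, the
multishell (slab-wall) nanotube, and the full non-decoupled nanotube with a
three-Gaussian bilayer wall profile.

Normalization convention
------------------------
Cross-section factors (``p_cross_uniform``, the multishell amplitude) are
per unit length: the uniform cylinder cross term is ``(rho pi R^2)^2`` at
q = 0.  Full intensities (``p_multishell``, ``p_coreshell_cylinder``,
``p_nanotube_gaussian_bilayer_full``) carry the length squared so that
P(0) equals the squared total excess scattering mass
(contrast x volume)^2.  This keeps every tube model in the package on a
common absolute scale, which the tube-limit cross-checks rely on.
Contrasts are always excess densities: solvent density is subtracted at
parameter ingestion, never inside the kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special
from scipy.interpolate import CubicSpline

from .curves import ScatteringCurve
from .exceptions import DegenerateContrastError, ModelDomainError
from .quadrature import axial_cross_average, gaussian_size_nodes, gl_nodes

__all__ = [
    "GaussianBilayerProfile",
    "NanotubeGaussianBilayerParams",
    "MultiShellParams",
    "CoreShellCylinderParams",
    "p_axial",
    "p_cross_uniform",
    "famp_multishell_cross",
    "p_multishell",
    "rho_gaussian_bilayer",
    "p_nanotube_gaussian_bilayer_full",
    "p_cylinder_radial_profile_full",
    "p_coreshell_cylinder",
]


# ---------------------------------------------------------------------------
# axial and uniform cross-section factors (decoupling approximation)

def p_axial(q, L: float):
    """Axial form-factor intensity of a long rod of length L.

    ``P_axial(q) = 2 Si(qL)/(qL) - 4 sin^2(qL/2)/(qL)^2``; equals 1 at
    q = 0 and decays as ``pi/(qL)`` for qL >> 1.  Valid as a factor of the
    total intensity when L >> R (decoupling approximation).
    """
    if L <= 0:
        raise ValueError("L must be positive")
    q = np.asarray(q, dtype=float)
    x = q * L
    small = x < 1e-6
    xs = np.where(small, 1.0, x)
    si, _ = special.sici(xs)
    out = 2.0 * si / xs - 4.0 * np.sin(xs / 2.0) ** 2 / xs ** 2
    # series: 1 - x^2/36 + ...
    out = np.where(small, 1.0 - x ** 2 / 36.0, out)
    return out if out.ndim else float(out)


def _two_j1_over_x(x):
    """2 J1(x)/x with its analytic q -> 0 limit (value 1)."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    xs = np.where(small, 1.0, x)
    out = 2.0 * special.j1(xs) / xs
    return np.where(small, 1.0 - x ** 2 / 8.0, out)


def p_cross_uniform(q, R: float, rho: float):
    """Cross-section intensity of a uniform cylinder of radius R.

    ``(rho pi R^2)^2 [2 J1(qR)/(qR)]^2`` per unit length; first zero at
    qR = 3.8317 (first root of J1).
    """
    if R <= 0:
        raise ValueError("R must be positive")
    q = np.asarray(q, dtype=float)
    out = (rho * np.pi * R ** 2) ** 2 * _two_j1_over_x(q * R) ** 2
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# multishell slab-wall nanotube

@dataclass
class MultiShellParams:
    """Concentric cylindrical shells: boundaries ``radii`` [A] (strictly
    increasing), excess contrasts ``rhos`` (one per shell, shell i spanning
    radii[i-1]..radii[i] with an implicit inner boundary at r = 0), length
    L [A], and a Gaussian polydispersity ``sigma_R`` applied as a rigid
    shift of all boundaries (wall thicknesses fixed, radius distributed)."""

    radii: np.ndarray
    rhos: np.ndarray
    L: float
    sigma_R: float = 0.0

    def __post_init__(self):
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        self.rhos = np.atleast_1d(np.asarray(self.rhos, dtype=float))
        if len(self.radii) != len(self.rhos):
            raise ValueError("radii and rhos must have the same length")
        if np.any(self.radii <= 0) or np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be positive and strictly increasing")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.sigma_R < 0:
            raise ValueError("sigma_R must be >= 0")

    # size parameter = outermost radius; polydispersity shifts rigidly
    @property
    def size_center(self) -> float:
        return float(self.radii[-1])

    def at_size(self, r: float) -> "MultiShellParams":
        shift = r - self.radii[-1]
        return replace(self, radii=self.radii + shift, sigma_R=0.0)

    def evaluate(self, q) -> np.ndarray:
        return p_multishell(q, self).I


def _contrast_steps(rhos: np.ndarray) -> np.ndarray:
    """Outward contrast steps Delta rho_i = rho_i - rho_{i+1} (solvent = 0)."""
    return rhos - np.append(rhos[1:], 0.0)


def shell_normalization(params: MultiShellParams) -> float:
    """C_shell = sum_i (rho_i - rho_{i+1}) R_i^2 (the q -> 0 amplitude scale)."""
    return float(np.sum(_contrast_steps(params.rhos) * params.radii ** 2))


def famp_multishell_cross(q, params: MultiShellParams):
    """Normalized cross-section amplitude of an N-shell tube.

    ``A(q) = sum_i (rho_i - rho_{i+1}) R_i^2 [2 J1(q R_i)/(q R_i)] / C_shell``
    with ``C_shell = sum_i (rho_i - rho_{i+1}) R_i^2``, so A(0) = 1 whenever
    the total excess scattering mass is nonzero.
    """
    c_shell = shell_normalization(params)
    if c_shell == 0.0:
        raise DegenerateContrastError(
            "total excess scattering mass is zero; C_shell normalization undefined"
        )
    q = np.asarray(q, dtype=float)
    steps = _contrast_steps(params.rhos)
    terms = steps[:, None] * params.radii[:, None] ** 2 \
        * _two_j1_over_x(np.multiply.outer(params.radii, q))
    out = terms.sum(axis=0) / c_shell
    return out if out.ndim else float(out)


def _mass_amplitude(q: np.ndarray, radii: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Unnormalized cross amplitude pi * sum_i drho_i R_i^2 g(q R_i) [mass/length]."""
    return np.pi * (steps[:, None] * radii[:, None] ** 2
                    * _two_j1_over_x(np.multiply.outer(radii, q))).sum(axis=0)


def p_multishell(q, params: MultiShellParams) -> ScatteringCurve:
    """Decoupled multishell nanotube intensity with radius polydispersity.

    ``P(q) = L^2 P_axial(q, L) < |pi sum_i drho_i R_i^2 g(q R_i)|^2 >_R``
    where the average runs over a Gaussian rigid shift of all shell
    boundaries (truncated so the innermost boundary stays positive,
    weights renormalized).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    steps = _contrast_steps(params.rhos)
    if np.all(steps == 0.0) and np.all(params.rhos == 0.0):
        raise DegenerateContrastError("all shell contrasts are zero")
    centers, weights = gaussian_size_nodes(
        params.size_center, params.sigma_R,
        lower=params.size_center - params.radii[0],  # keep innermost radius > 0
    )
    acc = np.zeros_like(q)
    for r_out, w in zip(centers, weights):
        radii = params.radii + (r_out - params.size_center)
        acc += w * _mass_amplitude(q, radii, steps) ** 2
    I = params.L ** 2 * p_axial(q, params.L) * acc
    return ScatteringCurve(q=q, I=I, label="multishell nanotube")


# ---------------------------------------------------------------------------
# Gaussian bilayer wall profile and the full (non-decoupled) nanotube

@dataclass
class GaussianBilayerProfile:
    """Three-Gaussian transverse contrast profile of a bilayer wall.

    A central (chain-core) Gaussian of amplitude ``rho_C`` (typically
    negative for lipids in water) and width ``sigma_C``, flanked by two
    headgroup Gaussians of amplitude ``rho_H`` and width ``sigma_H``
    centred a half bilayer thickness ``r_H`` either side of the wall
    centre."""

    rho_C: float
    sigma_C: float
    rho_H: float
    sigma_H: float
    r_H: float

    def __post_init__(self):
        if self.sigma_C <= 0 or self.sigma_H <= 0 or self.r_H <= 0:
            raise ValueError("sigma_C, sigma_H and r_H must be positive")


@dataclass
class NanotubeGaussianBilayerParams:
    """Nanotube whose wall carries a Gaussian bilayer radial profile.

    ``R`` is the radius to the wall centre [A] with Gaussian polydispersity
    ``sigma_R``; the wall occupies ``R - 2 r_H .. R + 2 r_H``."""

    R: float
    profile: GaussianBilayerProfile
    L: float
    sigma_R: float = 0.0

    def __post_init__(self):
        if self.R <= 2 * self.profile.r_H:
            raise ValueError("require R > 2 r_H (wall fully off-axis)")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.sigma_R < 0:
            raise ValueError("sigma_R must be >= 0")

    @property
    def size_center(self) -> float:
        return self.R

    def at_size(self, r: float) -> "NanotubeGaussianBilayerParams":
        return replace(self, R=r, sigma_R=0.0)

    def evaluate(self, q) -> np.ndarray:
        return p_nanotube_gaussian_bilayer_full(q, self).I


def rho_gaussian_bilayer(r, R: float, profile: GaussianBilayerProfile):
    """Radial contrast of a bilayer wall centred at radius R."""
    r = np.asarray(r, dtype=float)
    p = profile
    out = (p.rho_C * np.exp(-0.5 * ((r - R) / p.sigma_C) ** 2)
           + p.rho_H * np.exp(-0.5 * ((r - (R - p.r_H)) / p.sigma_H) ** 2)
           + p.rho_H * np.exp(-0.5 * ((r - (R + p.r_H)) / p.sigma_H) ** 2))
    return out if out.ndim else float(out)


def famp_radial_profile_cross(u, rho_fn, r_in: float, r_out: float,
                              n_radial: int = 400):
    """Cross-section amplitude ``2 pi int_{r_in}^{r_out} rho(r) J0(u r) r dr``.

    ``u`` is the radial wavenumber component; fixed-order Gauss-Legendre in
    r (default 400 nodes, dense enough for the J0 oscillations at the
    largest u used in this package).
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    r, w = gl_nodes(r_in, r_out, n_radial)
    weights = rho_fn(r) * r * w
    return 2.0 * np.pi * special.j0(np.multiply.outer(u, r)) @ weights


def p_cylinder_radial_profile_full(q, rho_fn, r_in: float, r_out: float,
                                   L: float, *, n_radial: int = 400,
                                   n_interp: int | None = None) -> ScatteringCurve:
    """Full (non-decoupled) orientational average for an arbitrary radial
    wall profile.

    ``P(q) = L^2 int_0^1 sinc^2(qLx/2) |F_cross(q sqrt(1-x^2))|^2 dx``
    with ``F_cross`` from :func:`famp_radial_profile_cross`.  The cross
    amplitude is tabulated on a dense u grid and spline-interpolated inside
    the tilt-angle quadrature.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    qmax = float(q.max())
    n_u = n_interp or max(512, int(16 * qmax * r_out / np.pi))
    u_grid = np.linspace(0.0, qmax, n_u)
    fc = famp_radial_profile_cross(u_grid, rho_fn, r_in, r_out, n_radial)
    spline = CubicSpline(u_grid, fc)

    def cross_sq(qr):
        return spline(qr) ** 2

    I = np.array([L ** 2 * axial_cross_average(cross_sq, qi, L, cross_scale=r_out)
                  for qi in q])
    return ScatteringCurve(q=q, I=I, label="full radial-profile nanotube")


def p_nanotube_gaussian_bilayer_full(q, params: NanotubeGaussianBilayerParams,
                                     *, n_radial: int = 400) -> ScatteringCurve:
    """Full nanotube intensity with a three-Gaussian bilayer wall.

    Outer integral over the tilt angle, inner radial integral of the
    profile against the J0 kernel over ``R +- 2 r_H``, then a Gaussian
    polydispersity average over R (rigid shift of the profile: wall
    thickness fixed, radius distributed).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    prof = params.profile
    centers, weights = gaussian_size_nodes(params.R, params.sigma_R,
                                           lower=2 * prof.r_H)
    I = np.zeros_like(q)
    for Rc, w in zip(centers, weights):
        curve = p_cylinder_radial_profile_full(
            q, lambda r, Rc=Rc: rho_gaussian_bilayer(r, Rc, prof),
            Rc - 2 * prof.r_H, Rc + 2 * prof.r_H, params.L, n_radial=n_radial)
        I += w * curve.I
    return ScatteringCurve(q=q, I=I, label="Gaussian-bilayer nanotube (full)")


# ---------------------------------------------------------------------------
# core-shell cylinder (the published long-cylindrical-shell component)

@dataclass
class CoreShellCylinderParams:
    """Long cylindrical shell: core radius R [A] (Gaussian polydispersity
    sigma_R), shell thickness s [A], densities of core, shell and solvent,
    length L [A].  Evaluated as the two-shell special case of the
    multishell model with solvent-subtracted contrasts."""

    R: float
    s: float
    rho_core: float
    rho_shell: float
    rho_solv: float
    L: float
    sigma_R: float = 0.0

    def __post_init__(self):
        if self.R <= 0 or self.s <= 0 or self.L <= 0:
            raise ValueError("R, s and L must be positive")
        if self.sigma_R < 0:
            raise ValueError("sigma_R must be >= 0")

    def to_multishell(self) -> MultiShellParams:
        return MultiShellParams(
            radii=np.array([self.R, self.R + self.s]),
            rhos=np.array([self.rho_core - self.rho_solv,
                           self.rho_shell - self.rho_solv]),
            L=self.L,
            sigma_R=self.sigma_R,
        )

    @property
    def size_center(self) -> float:
        return self.R

    def at_size(self, r: float) -> "CoreShellCylinderParams":
        if r <= 0:
            raise ModelDomainError("core radius must stay positive")
        return replace(self, R=r, sigma_R=0.0)

    def evaluate(self, q) -> np.ndarray:
        return p_coreshell_cylinder(q, self).I


def p_coreshell_cylinder(q, params: CoreShellCylinderParams) -> ScatteringCurve:
    """Decoupled core-shell cylinder intensity (see :func:`p_multishell`)."""
    curve = p_multishell(q, params.to_multishell())
    return replace(curve, label="core-shell cylinder")
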