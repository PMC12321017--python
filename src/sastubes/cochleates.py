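"""Cochleate (rolled-sheet) form factors.

A cochleate is an infinitesimally thin sheet rolled into an Archimedean
spiral: a surface point is ``(D phi cos phi, D phi sin phi, z)`` with the
winding angle phi running over m turns and z spanning the axial extent
delta.  The rolled layer has repeat ``2 pi D``, which produces quasi-Bragg
peaks at multiples of ``q = 1/D`` that sharpen as the number of turns m
grows.  The helical cochleate advances axially along the spiral,
``(D phi cos phi, D phi sin phi, z + p phi)`` with p the pitch per radian
of winding.

The oriented amplitudes are winding-angle quadratures with the true
surface measure ``D sqrt(1 + phi^2) dphi dz`` (so the q = 0 amplitude is
the sheet mass: density x arc length x delta).  The isotropic average
exploits two structural facts: the axial integral separates into a
``sinc`` factor, and for the plain cochleate the azimuthally averaged
squared cross amplitude H depends only on the in-plane wavenumber q_r.
H is therefore tabulated once on a q_r grid - the azimuthal average is
evaluated exactly by uniform sampling, since the amplitude is bandlimited
in the azimuth by the Jacobi-Anger expansion - and spline-interpolated
inside the tilt-angle quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .curves import ScatteringCurve
from .quadrature import axial_cross_average, gl_nodes, sinc_half

__all__ = [
    "CochleateParams",
    "famp_cochleate_oriented",
    "famp_helical_cochleate_oriented",
    "p_cochleate_iso",
]


@dataclass
class CochleateParams:
    """Archimedean-spiral rolled sheet.

    D: spiral growth parameter [A] (layer repeat 2 pi D); m: number of
    turns; delta: axial extent [A]; p: helical pitch per radian of winding
    [A/rad], 0 for a plain cochleate; rho: uniform density [arb.];
    phi0: inner winding offset [rad] (0 starts the spiral at the origin).
    """

    D: float
    m: int
    delta: float = 2000.0
    p: float = 0.0
    rho: float = 1.0
    phi0: float = 0.0

    def __post_init__(self):
        if self.D <= 0 or self.delta <= 0:
            raise ValueError("D and delta must be positive")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.p < 0:
            raise ValueError("p must be >= 0")
        if self.phi0 < 0:
            raise ValueError("phi0 must be >= 0")

    @property
    def phi_max(self) -> float:
        return self.phi0 + 2 * np.pi * self.m

    def arc_length(self) -> float:
        """Length of the spiral cross-section curve."""
        phi, w = gl_nodes(self.phi0, self.phi_max, 400)
        return float(self.D * np.sum(w * np.sqrt(1 + phi ** 2)))

    def evaluate(self, q) -> np.ndarray:
        return p_cochleate_iso(q, self).I


def _phi_rule(params: CochleateParams, qr: float, axial_coeff: float = 0.0):
    """Winding-angle Gauss rule sized to the phase oscillation count.

    ``axial_coeff`` is the linear phase per radian of winding (|q_z| p for
    helical cochleates)."""
    pm = params.phi_max
    cycles = (qr * params.D * (pm + 0.5 * pm * pm)
              + abs(axial_coeff) * pm) / (2 * np.pi)
    n = int(min(max(256, 6 * np.ceil(cycles + 1)), 40000))
    return gl_nodes(params.phi0, pm, n)


def _famp(q: float, theta: float, chi: float, params: CochleateParams,
          pitch: float) -> complex:
    qz = q * np.cos(theta)
    qr = q * np.sin(theta)
    phi, w = _phi_rule(params, qr, abs(qz) * pitch)
    g = params.rho * params.D * np.sqrt(1 + phi ** 2)
    phase = qr * params.D * phi * np.cos(phi - chi) + qz * pitch * phi
    cross = np.sum(w * g * np.exp(1j * phase))
    return params.delta * sinc_half(0.5 * qz * params.delta) * cross


def famp_cochleate_oriented(q: float, theta: float, chi: float,
                            params: CochleateParams) -> complex:
    """Oriented complex amplitude of a plain cochleate (requires p = 0)."""
    if params.p != 0:
        raise ValueError("plain cochleate requires p = 0; "
                         "use famp_helical_cochleate_oriented")
    return _famp(q, theta, chi, params, 0.0)


def famp_helical_cochleate_oriented(q: float, theta: float, chi: float,
                                    params: CochleateParams) -> complex:
    """Oriented complex amplitude of a helical cochleate (axial phase
    advanced by p*phi along the spiral; continuous in p at p = 0)."""
    return _famp(q, theta, chi, params, params.p)


def _cross_avg_sq(qr: float, params: CochleateParams, qz_pitch: float = 0.0,
                  chi_chunk: int = 128) -> float:
    """Azimuthal average of the squared cross amplitude at radial
    wavenumber qr (and, for helical cochleates, axial phase qz*p).

    The cross amplitude is bandlimited in the azimuth chi to harmonics
    |k| <= K with K set by the largest Bessel argument qr*D*phi_max, so
    the mean over uniform chi samples is exact (to the Jacobi-Anger
    truncation): 2K+1 samples on [0, 2 pi), or - for a real density,
    where F(chi + pi) = conj(F(chi)) makes |F|^2 pi-periodic - K+1
    samples on [0, pi)."""
    K = int(np.ceil(qr * params.D * params.phi_max)) + 12
    phi, w = _phi_rule(params, qr, qz_pitch)
    # the pitch phase does not depend on chi; fold it into the weights
    g = params.rho * params.D * np.sqrt(1 + phi ** 2) * w
    base = np.exp(1j * qz_pitch * phi)
    if qz_pitch == 0.0:
        n_chi = K + 4
        chis = np.pi * np.arange(n_chi) / n_chi
    else:
        n_chi = 2 * K + 1
        chis = 2 * np.pi * np.arange(n_chi) / n_chi
    acc = 0.0
    arg = qr * params.D * phi
    for start in range(0, n_chi, chi_chunk):
        c = chis[start:start + chi_chunk]
        phase = arg[None, :] * np.cos(phi[None, :] - c[:, None])
        F = (np.exp(1j * phase) * (g * base)[None, :]).sum(axis=1)
        acc += float(np.sum(np.abs(F) ** 2))
    return acc / n_chi


def p_cochleate_iso(q, params: CochleateParams, *,
                    table_points: int | None = None) -> ScatteringCurve:
    """Isotropically averaged intensity of a (possibly helical) cochleate.

    Plain cochleates (p = 0) use a spline table of the azimuthally
    averaged cross intensity H(q_r), dense enough to resolve the
    quasi-Bragg peaks of width ~ 1/(D m); helical cochleates evaluate H
    pointwise inside the tilt quadrature (much slower - intended for
    small q grids).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    qmax = float(q.max())
    outer = params.D * params.phi_max

    if params.p == 0.0:
        n_tab = table_points or int(np.clip(12 * qmax * params.D * params.m, 96, 384))
        qr_grid = np.linspace(0.0, qmax, n_tab)
        H = np.array([_cross_avg_sq(qr, params) for qr in qr_grid])
        spline = CubicSpline(qr_grid, H)

        def cross_sq(qr):
            return np.clip(spline(qr), 0.0, None)

        I = np.array([
            params.delta ** 2 * axial_cross_average(
                cross_sq, qi, params.delta, cross_scale=outer,
                max_resolved_lobes=400)
            for qi in q])
    else:
        I = np.empty_like(q)
        for i, qi in enumerate(q):
            def cross_sq(qr_arr, qi=qi):
                qr_arr = np.atleast_1d(qr_arr)
                qz = np.sqrt(np.clip(qi ** 2 - qr_arr ** 2, 0.0, None))
                return np.array([
                    _cross_avg_sq(qr, params, qz_pitch=z * params.p)
                    for qr, z in zip(qr_arr, qz)])

            I[i] = params.delta ** 2 * axial_cross_average(
                cross_sq, qi, params.delta, cross_scale=outer,
                max_resolved_lobes=40)
    return ScatteringCurve(q=q, I=I, label="cochleate")
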