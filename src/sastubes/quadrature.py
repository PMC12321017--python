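"""Shared quadrature machinery.

Every orientational average in this package reduces to integrals of the form

    integral_0^1  sinc^2(q L x / 2) * H(q sqrt(1 - x^2)) dx

where ``x = cos(theta)`` is the cosine of the tilt angle between the particle
axis and the scattering vector, L is the particle length and H is the
azimuthally averaged squared cross-section amplitude.  The axial factor
``sinc^2`` oscillates with lobe width ``2 pi / (q L)`` which for long
particles (L up to 10^6 A) is far too fine for a single Gauss rule, so the
integral is panelized lobe by lobe near x = 0 and, beyond a configurable
number of resolved lobes, the rapidly oscillating ``sin^2`` is replaced by
its mean 1/2 (the envelope ``2 / (q L x)^2``), which is accurate to
O(1/(qL)) in the tail.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss


@lru_cache(maxsize=128)
def _leggauss(n: int):
    x, w = leggauss(n)
    return x, w


def gl_nodes(a: float, b: float, n: int):
    """Gauss-Legendre nodes and weights on [a, b].

    Large rules are assembled by tiling a cached 24-point rule over equal
    panels: computing a single high-order rule costs O(n^2) in node
    generation and brings no benefit for the oscillatory integrands used
    here, where panels at a fixed number of nodes per oscillation are the
    natural discretization.
    """
    n = int(n)
    if n <= 64:
        x, w = _leggauss(n)
        half = 0.5 * (b - a)
        return a + half * (x + 1.0), half * w
    order = 24
    panels = (n + order - 1) // order
    edges = np.linspace(a, b, panels + 1)
    x0, w0 = _leggauss(order)
    half = 0.5 * (edges[1] - edges[0])
    centers = 0.5 * (edges[:-1] + edges[1:])
    nodes = (centers[:, None] + half * x0[None, :]).ravel()
    weights = np.broadcast_to(half * w0, (panels, order)).ravel()
    return nodes, weights.copy()


def oscillatory_gl(a: float, b: float, cycles: float, nodes_per_cycle: int = 8,
                   n_min: int = 32, n_max: int = 60000):
    """Nodes/weights for an integrand with ~``cycles`` oscillations on [a, b].

    Uses a single Gauss-Legendre rule with enough points to oversample the
    fastest oscillation; Gauss rules resolve ~n/pi cycles, so
    ``nodes_per_cycle >= 6`` gives generous headroom.
    """
    n = int(np.clip(n_min, *(None, None)) if False else max(n_min, int(np.ceil(nodes_per_cycle * max(cycles, 1.0)))))
    n = min(n, n_max)
    return gl_nodes(a, b, n)


def sinc_half(x):
    """sin(x)/x with the removable singularity handled (equals 1 at x=0)."""
    return np.sinc(np.asarray(x) / np.pi)


def axial_cross_average(cross_sq, q: float, length: float, *,
                        cross_scale: float = 0.0,
                        nodes_per_lobe: int = 8,
                        max_resolved_lobes: int = 400):
    """``integral_0^1 sinc^2(q*length*x/2) * cross_sq(q*sqrt(1-x^2)) dx``.

    Parameters
    ----------
    cross_sq : callable
        Vectorized function of the radial wavenumber component
        ``q_r = q sqrt(1-x^2)`` returning the azimuthally averaged squared
        cross-section amplitude.
    q, length : float
        Wavenumber [1/A] and particle length [A].
    cross_scale : float
        Largest radial length scale in the cross section; controls the node
        count used to resolve oscillations of ``cross_sq`` in the tail.
    """
    qL = q * length
    if qL <= 2.0 * np.pi:
        x, w = gl_nodes(0.0, 1.0, max(64, int(10 * q * cross_scale)))
        return float(np.sum(w * sinc_half(0.5 * qL * x) ** 2
                            * cross_sq(q * np.sqrt(np.clip(1 - x * x, 0.0, None)))))

    lobe = 2.0 * np.pi / qL
    n_lobes = int(np.floor(1.0 / lobe))
    n_resolved = min(n_lobes, max_resolved_lobes)

    xs = []
    ws = []
    # main lobe gets extra nodes; subsequent lobes one small rule each
    x0, w0 = gl_nodes(0.0, lobe, 2 * nodes_per_lobe)
    xs.append(x0)
    ws.append(w0)
    for j in range(1, n_resolved):
        xj, wj = gl_nodes(j * lobe, (j + 1) * lobe, nodes_per_lobe)
        xs.append(xj)
        ws.append(wj)
    x = np.concatenate(xs)
    w = np.concatenate(ws)
    total = float(np.sum(w * sinc_half(0.5 * qL * x) ** 2
                         * cross_sq(q * np.sqrt(np.clip(1 - x * x, 0.0, None)))))

    x_end = n_resolved * lobe
    if x_end < 1.0:
        if n_resolved < n_lobes:
            # unresolved tail: replace sin^2 by its mean 1/2
            n_tail = max(96, int(10 * q * cross_scale))
            xt, wt = gl_nodes(x_end, 1.0, n_tail)
            env = 2.0 / (qL * xt) ** 2
            total += float(np.sum(wt * env *
                                  cross_sq(q * np.sqrt(np.clip(1 - xt * xt, 0.0, None)))))
        else:
            xt, wt = gl_nodes(x_end, 1.0, max(nodes_per_lobe, int(10 * q * cross_scale * (1 - x_end))))
            total += float(np.sum(wt * sinc_half(0.5 * qL * xt) ** 2
                                  * cross_sq(q * np.sqrt(np.clip(1 - xt * xt, 0.0, None)))))
    return total


def gaussian_size_nodes(center: float, width: float, *, lower: float | None = None,
                        n: int = 51, n_sigma: float = 5.0):
    """Quadrature nodes/weights for a Gaussian size distribution.

    Fixed-order Gauss-Legendre rule over ``center +- n_sigma*width``, truncated
    at ``lower`` (exclusive) when given, with weights renormalized to unit
    total probability after truncation.  ``width == 0`` returns the single
    node ``center`` with weight 1.
    """
    if width < 0:
        raise ValueError("width must be >= 0")
    if width == 0.0:
        if lower is not None and center <= lower:
            raise ValueError("distribution center outside the valid domain")
        return np.array([center]), np.array([1.0])
    a = center - n_sigma * width
    b = center + n_sigma * width
    if lower is not None:
        if b <= lower:
            raise ValueError("distribution support entirely outside the valid domain")
        a = max(a, lower * (1.0 + 1e-12))
    r, w = gl_nodes(a, b, n)
    pdf = np.exp(-0.5 * ((r - center) / width) ** 2)
    weights = w * pdf
    weights /= weights.sum()
    return r, weights
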