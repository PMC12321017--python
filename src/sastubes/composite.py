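"""Composite model assembly.

The fit structure used throughout the package:

    I(q) = I0 * sum_i w_i P_i(q) S_i(q) + C

a weighted sum of form-factor components, each optionally multiplied by a
structure factor, plus a constant background C and overall scale I0.  The
standard two-component fit pairs a hollow cylinder (the nanotube envelope,
low-q fringes) with a flat Gaussian bilayer (the wall structure, high-q
features), the latter optionally carrying the Caille lamellar factor.
Treating the bilayer as a separate additive flat component is the
computationally cheap alternative to the full non-decoupled nanotube
model, which remains available behind the same interface for validation.

Also here: the generic Gaussian size-polydispersity average and the flat
Gaussian bilayer form factor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .curves import ScatteringCurve
from .exceptions import ModelDomainError
from .quadrature import gaussian_size_nodes

__all__ = [
    "SizeDistribution",
    "average_over_size",
    "FlatGaussianBilayerParams",
    "p_flat_gaussian_bilayer",
    "Component",
    "CompositeModel",
    "evaluate_composite",
]


@dataclass
class SizeDistribution:
    """Gaussian size distribution (centre R, width sigma)."""

    center: float
    width: float
    kind: str = "gaussian"

    def __post_init__(self):
        if self.kind != "gaussian":
            raise ValueError("only gaussian size distributions are supported")
        if self.width < 0:
            raise ValueError("width must be >= 0")

    def nodes(self, lower: float | None = None, n: int = 51):
        return gaussian_size_nodes(self.center, self.width, lower=lower, n=n)


def average_over_size(model, dist: SizeDistribution, q,
                      lower: float | None = None) -> ScatteringCurve:
    """Polydispersity average ``< P(q; r) >`` over a Gaussian size
    distribution.

    ``model`` must expose ``at_size(r)`` (returning a monodisperse copy at
    size r) and ``evaluate(q)``.  The distribution support is truncated at
    ``lower`` (weights renormalized); a support entirely outside the valid
    domain raises :class:`ModelDomainError`.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    try:
        r_nodes, weights = dist.nodes(lower=lower)
    except ValueError as exc:
        raise ModelDomainError(str(exc)) from exc
    I = np.zeros_like(q)
    for r, w in zip(r_nodes, weights):
        I += w * model.at_size(r).evaluate(q)
    return ScatteringCurve(q=q, I=I, label="size-averaged model")


# ---------------------------------------------------------------------------
# flat Gaussian bilayer (decoupled lamellar component)

@dataclass
class FlatGaussianBilayerParams:
    """Flat (lamellar) bilayer with a three-Gaussian transverse profile.

    t: layer thickness [A] (headgroup-to-headgroup) with Gaussian
    polydispersity dt; rho_H/sigma_H and rho_C/sigma_C as in the nanotube
    wall profile; D: lateral diameter of the layer [A].  For D >> t the
    lateral extent only scales the intensity, so D is folded into the
    component weight and does not enter the kernel.
    """

    t: float
    rho_H: float
    sigma_H: float
    rho_C: float
    sigma_C: float
    dt: float = 0.0
    D: float | None = None

    def __post_init__(self):
        if self.t <= 0:
            raise ValueError("t must be positive")
        if self.sigma_H <= 0 or self.sigma_C <= 0:
            raise ValueError("sigma_H and sigma_C must be positive")
        if self.dt < 0:
            raise ValueError("dt must be >= 0")
        if self.D is not None and self.D <= 0:
            raise ValueError("D must be positive")

    @property
    def size_center(self) -> float:
        return self.t

    def at_size(self, r: float) -> "FlatGaussianBilayerParams":
        return replace(self, t=r, dt=0.0)

    def evaluate(self, q) -> np.ndarray:
        return p_flat_gaussian_bilayer(q, self).I


def bilayer_transverse_amplitude(q, params: FlatGaussianBilayerParams,
                                 t: float | None = None) -> np.ndarray:
    """1D Fourier transform of the symmetric three-Gaussian profile.

    ``F(q) = sqrt(2 pi) [ rho_C sigma_C exp(-q^2 sigma_C^2/2)
    + 2 rho_H sigma_H exp(-q^2 sigma_H^2/2) cos(q t/2) ]`` (real, since
    the profile is symmetric about the bilayer centre)."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    t = params.t if t is None else t
    root = np.sqrt(2 * np.pi)
    return root * (params.rho_C * params.sigma_C * np.exp(-0.5 * (q * params.sigma_C) ** 2)
                   + 2 * params.rho_H * params.sigma_H
                   * np.exp(-0.5 * (q * params.sigma_H) ** 2) * np.cos(0.5 * q * t))


def p_flat_gaussian_bilayer(q, params: FlatGaussianBilayerParams) -> ScatteringCurve:
    """Decoupled flat-bilayer intensity ``< |F(q; t)|^2 > / q^2``.

    The ``q^-2`` prefactor is the lamellar (Lorentz) factor of a randomly
    oriented extended sheet; the Kratky transform of this component is the
    slowly varying squared profile transform itself.  Thickness
    polydispersity dt is averaged with the shared Gaussian rule.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q <= 0):
        raise ValueError("flat-bilayer intensity requires q > 0")
    t_nodes, weights = gaussian_size_nodes(params.t, params.dt, lower=0.0)
    F2 = np.zeros_like(q)
    for t, w in zip(t_nodes, weights):
        F2 += w * bilayer_transverse_amplitude(q, params, t=t) ** 2
    return ScatteringCurve(q=q, I=F2 / q ** 2, label="flat Gaussian bilayer")


# ---------------------------------------------------------------------------
# composite model

@dataclass
class Component:
    """One additive term: weight x form factor x optional structure factor."""

    weight: float
    form: object
    sf: object | None = None

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("component weights must be >= 0")
        if not hasattr(self.form, "evaluate"):
            raise TypeError("form must expose an evaluate(q) method")
        if self.sf is not None and not hasattr(self.sf, "evaluate"):
            raise TypeError("sf must expose an evaluate(q) method")


@dataclass
class CompositeModel:
    """``I(q) = I0 sum_i w_i P_i(q) S_i(q) + C``."""

    components: list
    background: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        if not self.components:
            raise ValueError("at least one component is required")
        self.components = [c if isinstance(c, Component) else Component(*c)
                           for c in self.components]

    def evaluate(self, q) -> ScatteringCurve:
        return evaluate_composite(self, q)

    def evaluate_components(self, q) -> list[np.ndarray]:
        """Per-component contributions w_i P_i S_i (before scale/background)."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        out = []
        for comp in self.components:
            term = comp.weight * np.asarray(comp.form.evaluate(q), dtype=float)
            if term.shape != q.shape:
                raise ValueError("component returned a grid-mismatched array")
            if comp.sf is not None:
                s = np.asarray(comp.sf.evaluate(q), dtype=float)
                if s.shape != q.shape:
                    raise ValueError("structure factor returned a grid-mismatched array")
                term = term * s
            out.append(term)
        return out

    # -- parameter addressing -------------------------------------------------
    _PATH_RE = re.compile(r"^components\[(\d+)\]\.(weight|form|sf)(?:\.(.+))?$")

    def _resolve(self, path: str):
        """Return (owner object, attribute name) for a parameter path.

        Paths: ``scale``, ``background``, ``components[i].weight``,
        ``components[i].form.<attr>[.<attr>]``, ``components[i].sf.<attr>``.
        """
        if path in ("scale", "background"):
            return self, path
        m = self._PATH_RE.match(path)
        if not m:
            raise KeyError(f"unrecognized parameter path {path!r}")
        idx = int(m.group(1))
        if idx >= len(self.components):
            raise KeyError(f"{path!r}: component index out of range")
        comp = self.components[idx]
        kind, rest = m.group(2), m.group(3)
        if kind == "weight":
            if rest:
                raise KeyError(f"{path!r}: weight takes no sub-attribute")
            return comp, "weight"
        obj = comp.form if kind == "form" else comp.sf
        if obj is None:
            raise KeyError(f"{path!r}: component has no structure factor")
        if not rest:
            raise KeyError(f"{path!r}: missing attribute name")
        parts = rest.split(".")
        for part in parts[:-1]:
            if not hasattr(obj, part):
                raise KeyError(f"{path!r}: no attribute {part!r}")
            obj = getattr(obj, part)
        if not hasattr(obj, parts[-1]):
            raise KeyError(f"{path!r}: no attribute {parts[-1]!r}")
        return obj, parts[-1]

    def get_param(self, path: str) -> float:
        obj, attr = self._resolve(path)
        value = getattr(obj, attr)
        if not np.isscalar(value):
            raise KeyError(f"{path!r} does not resolve to a scalar parameter")
        return float(value)

    def set_param(self, path: str, value: float) -> None:
        obj, attr = self._resolve(path)
        if not np.isscalar(getattr(obj, attr)):
            raise KeyError(f"{path!r} does not resolve to a scalar parameter")
        setattr(obj, attr, float(value))
        post = getattr(obj, "__post_init__", None)
        if post is not None:
            post()  # re-validate invariants


def evaluate_composite(model: CompositeModel, q) -> ScatteringCurve:
    """Evaluate the composite intensity on a q grid."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    total = sum(model.evaluate_components(q))
    I = model.scale * total + model.background
    return ScatteringCurve(q=q, I=I, label="composite model")
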