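"""Inter-layer structure factors.

Dilute nanotube solutions need no inter-particle term (S = 1); multilayer
tape/ribbon populations coexisting with the tubes show lamellar quasi-Bragg
peaks described by the Caille model of thermally fluctuating stacks.  The
paper-style fits multiply the Caille factor into the flat-bilayer component
of a composite model only, never into the hollow-cylinder component.

The implemented form is the modified Caille theory for a finite stack of N
layers with repeat d and fluctuation parameter eta (per layer, i.e.
normalized to 1 for an uncorrelated stack at high q):

    S(q) = 1 + (2/N) sum_{k=1}^{N-1} (N - k) cos(k q d)
           exp( -(d q / 2 pi)^2 eta [ gamma_E + ln(pi k) ] )

The additional diffuse-scattering weight nu admixes an uncorrelated
fraction; two conventions are provided and the choice is explicit:
``"normalized"`` gives (S + nu)/(1 + nu) (default), ``"additive"`` gives
S + nu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CailleParams", "s_unity", "s_caille"]

_EULER_GAMMA = float(np.euler_gamma)


def s_unity(q) -> np.ndarray:
    """Unit structure factor (non-interacting particles)."""
    return np.ones_like(np.atleast_1d(np.asarray(q, dtype=float)))


@dataclass
class CailleParams:
    """Lamellar stack: N correlated layers, repeat d [A], Caille
    fluctuation parameter eta (dimensionless), diffuse weight nu."""

    N: int
    d: float
    eta: float
    nu: float = 0.0
    diffuse: str = "normalized"

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.d <= 0:
            raise ValueError("d must be positive")
        if self.eta < 0 or self.nu < 0:
            raise ValueError("eta and nu must be >= 0")
        if self.diffuse not in ("normalized", "additive"):
            raise ValueError("diffuse must be 'normalized' or 'additive'")

    def evaluate(self, q) -> np.ndarray:
        return s_caille(q, self)


def s_caille(q, params: CailleParams) -> np.ndarray:
    """Modified Caille structure factor, per layer (see module docstring).

    Peaks near ``q = 2 pi n / d`` broaden and shrink with increasing eta;
    S -> N at q -> 0 and S -> 1 at high q.  N = 1 gives identically 1.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    N, d, eta = params.N, params.d, params.eta
    S = np.ones_like(q)
    if N > 1:
        acc = np.zeros_like(q)
        qd2 = (d * q / (2 * np.pi)) ** 2
        for k in range(1, N):
            damp = np.exp(-qd2 * eta * (_EULER_GAMMA + np.log(np.pi * k)))
            acc += (N - k) * np.cos(k * q * d) * damp
        S = S + 2.0 * acc / N
    if params.nu:
        if params.diffuse == "normalized":
            S = (S + params.nu) / (1.0 + params.nu)
        else:
            S = S + params.nu
    return S
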