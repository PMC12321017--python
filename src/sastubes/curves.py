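"""1D reduced scattering curves: the universal exchange object.

A curve is the triple (q, I, sigma) with q in reciprocal angstroms and I in
arbitrary units; sigma is the optional propagated 1-sigma uncertainty of I.
Files are the de-facto reduced small-angle scattering ASCII dialect: two or
three numeric columns (q, I[, sigma]), '#' comment lines, whitespace or
comma delimited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import CurveFormatError, EmptyDataError, EmptyWindowError

logger = logging.getLogger(__name__)

__all__ = [
    "ScatteringCurve",
    "read_curve",
    "write_curve",
    "kratky_transform",
    "crop_q",
]


@dataclass
class ScatteringCurve:
    """Reduced 1D scattering curve.

    Attributes
    ----------
    q : ndarray
        Wavenumber [1/A]; strictly increasing, finite, positive.
    I : ndarray
        Intensity [arbitrary units], same length as q.
    sigma : ndarray or None
        Intensity uncertainty, all positive when present.
    label : str
        Free-text provenance (sample name, header metadata).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.I.ndim != 1:
            raise ValueError("q and I must be 1-dimensional")
        if len(self.q) != len(self.I):
            raise ValueError("q and I must have the same length")
        if self.sigma is not None and len(self.sigma) != len(self.q):
            raise ValueError("sigma must have the same length as q")
        if len(self.q) == 0:
            raise EmptyDataError("curve has no points")
        if not np.all(np.isfinite(self.q)):
            raise ValueError("q contains non-finite values")
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None and np.any(self.sigma <= 0):
            raise ValueError("sigma values must be positive")

    def __len__(self) -> int:
        return len(self.q)

    def kratky(self) -> "ScatteringCurve":
        """Return the Kratky representation I*q^2 of this curve."""
        return kratky_transform(self)

    def crop(self, qmin: float, qmax: float) -> "ScatteringCurve":
        return crop_q(self, qmin, qmax)

    def plot(self, ax=None, kratky: bool = False, **kwargs):
        """Plot the curve (log-log, or I*q^2 vs log q when ``kratky``)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.kratky() if kratky else self
        kwargs.setdefault("label", self.label or None)
        if c.sigma is not None:
            ax.errorbar(c.q, c.I, yerr=c.sigma, **kwargs)
        else:
            ax.plot(c.q, c.I, **kwargs)
        ax.set_xscale("log")
        if not kratky:
            ax.set_yscale("log")
        ax.set_xlabel(r"$q$ [$\mathrm{\AA}^{-1}$]")
        ax.set_ylabel(r"$Iq^2$ [arb.]" if kratky else r"$I$ [arb.]")
        return ax


def _parse_rows(path, dialect: str):
    rows = []
    meta = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                # '# key: value' header metadata is kept verbatim in the label
                if ":" in body and body:
                    meta.append(body)
                continue
            if dialect == "csv":
                parts = [p for p in stripped.replace(",", " ").split() if p]
            else:
                parts = stripped.split()
            if len(parts) < 2:
                raise CurveFormatError(
                    f"{path}:{lineno}: expected >= 2 numeric columns, got {len(parts)}"
                )
            try:
                values = [float(p) for p in parts[:3]]
            except ValueError as exc:
                raise CurveFormatError(f"{path}:{lineno}: non-numeric field") from exc
            rows.append(values)
    return rows, meta


def read_curve(path, dialect: str = "whitespace") -> ScatteringCurve:
    """Read a reduced-data ASCII curve.

    Rows with non-positive q or any non-finite value are dropped (with a
    logged count); rows are sorted ascending in q and exact duplicate q
    values are averaged (sigmas combined in quadrature).
    """
    if dialect not in ("whitespace", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows, meta = _parse_rows(path, dialect)
    if not rows:
        raise EmptyDataError(f"{path}: no data rows")
    ncols = min(len(r) for r in rows)
    data = np.array([r[:ncols] for r in rows], dtype=float)
    valid = (data[:, 0] > 0) & np.all(np.isfinite(data), axis=1)
    if ncols >= 3:
        valid &= data[:, 2] > 0
    dropped = int(np.sum(~valid))
    if dropped:
        logger.info("read_curve(%s): dropped %d invalid row(s)", path, dropped)
    data = data[valid]
    if data.shape[0] == 0:
        raise EmptyDataError(f"{path}: no valid data rows after filtering")
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]

    q, idx = np.unique(data[:, 0], return_inverse=True)
    if len(q) != data.shape[0]:
        counts = np.bincount(idx)
        I = np.bincount(idx, weights=data[:, 1]) / counts
        sigma = None
        if ncols >= 3:
            sigma = np.sqrt(np.bincount(idx, weights=data[:, 2] ** 2)) / counts
    else:
        I = data[:, 1]
        sigma = data[:, 2] if ncols >= 3 else None
    label = "; ".join(meta)
    return ScatteringCurve(q=q, I=I, sigma=sigma, label=label)


def write_curve(curve: ScatteringCurve, path, header: dict | None = None) -> None:
    """Write a curve in the package ASCII dialect (16 significant digits)."""
    with open(path, "w", encoding="utf-8") as fh:
        if curve.label:
            fh.write(f"# label: {curve.label}\n")
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("# columns: q[1/A] I[arb]" + (" sigma[arb]" if curve.sigma is not None else "") + "\n")
        cols = [curve.q, curve.I] + ([curve.sigma] if curve.sigma is not None else [])
        np.savetxt(fh, np.column_stack(cols), fmt="%.15e")


def kratky_transform(curve: ScatteringCurve) -> ScatteringCurve:
    """Kratky (Lorentz-corrected) representation: I -> I*q^2, sigma -> sigma*q^2.

    Flattens the q^-2 tail of lamellar scatterers and exposes the
    form-factor oscillations of large tubes.
    """
    q2 = curve.q ** 2
    return replace(
        curve,
        I=curve.I * q2,
        sigma=None if curve.sigma is None else curve.sigma * q2,
    )


def crop_q(curve: ScatteringCurve, qmin: float, qmax: float) -> ScatteringCurve:
    """Restrict a curve to qmin <= q <= qmax (inclusive)."""
    if not qmin < qmax:
        raise ValueError("require qmin < qmax")
    mask = (curve.q >= qmin) & (curve.q <= qmax)
    if not np.any(mask):
        raise EmptyWindowError(
            f"window [{qmin}, {qmax}] contains no data points "
            f"(data span [{curve.q[0]}, {curve.q[-1]}])"
        )
    return replace(
        curve,
        q=curve.q[mask],
        I=curve.I[mask],
        sigma=None if curve.sigma is None else curve.sigma[mask],
    )
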