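"""Error-weighted least-squares fitting of composite models.

Follows the fit-object idiom of the statistical-modelling ecosystem: a
:class:`FitProblem` binds data, model and free/fixed parameter
declarations; its :meth:`FitProblem.fit` returns a :class:`FitResult`
carrying best-fit values, indicative uncertainties, chi-square diagnostics
and a printable parameter table.

The objective is the experimental-error-weighted chi-square

    chi^2 = sum_j [ (I_obs(q_j) - I_model(q_j)) / sigma_j ]^2

minimized by bounded trust-region-reflective least squares.  Parameters
with strictly positive lower bounds (radii, thicknesses, widths) are
fitted in log space internally, which enforces positivity and avoids
boundary sticking; results are reported in linear space.  Optimization is
deterministic given (start, seed); the optional multi-start draws extra
starting points uniformly inside the bounds from the seeded generator.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .composite import CompositeModel
from .curves import ScatteringCurve, crop_q
from .exceptions import EmptyWindowError

logger = logging.getLogger(__name__)

__all__ = ["FitProblem", "FitResult", "chi2", "fit"]


def chi2(curve: ScatteringCurve, model: CompositeModel,
         q_window: tuple | None = None,
         missing_sigma: str = "unit") -> float:
    """Weighted chi-square of a model against a curve.

    Points with sigma = 0 are excluded (degenerate error bars are
    reduction artifacts); a curve without a sigma column falls back to
    unit weights with a warning when ``missing_sigma == "unit"`` and
    raises otherwise.
    """
    if q_window is not None:
        curve = crop_q(curve, *q_window)
    I_model = model.evaluate(curve.q).I
    if curve.sigma is None:
        if missing_sigma != "unit":
            raise ValueError("curve has no sigma column")
        warnings.warn("curve has no uncertainties; using unit weights")
        sigma = np.ones_like(curve.I)
    else:
        sigma = curve.sigma
    good = sigma > 0
    if not np.all(good):
        warnings.warn(f"excluding {int(np.sum(~good))} point(s) with sigma = 0")
    r = (curve.I[good] - I_model[good]) / sigma[good]
    return float(np.dot(r, r))


@dataclass
class FitResult:
    """Best-fit parameters and diagnostics.

    ``params`` maps each free parameter path to its best-fit value;
    ``stderr`` holds indicative 1-sigma uncertainties from the local
    Jacobian (not a full error analysis).  ``chi2``/``dof`` are the
    weighted residual sum of squares and points-minus-parameters.
    """

    params: dict
    stderr: dict
    fixed: dict
    chi2: float
    dof: int
    residuals: np.ndarray
    success: bool
    message: str
    nfev: int
    model: CompositeModel
    start: dict

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / self.dof

    def summary(self) -> str:
        """Parameter table in the style of a published fit-parameter table."""
        lines = [
            "Weighted least-squares fit",
            "=" * 58,
            f"{'parameter':<34}{'value':>14}  status",
            "-" * 58,
        ]
        for name, value in self.params.items():
            err = self.stderr.get(name)
            err_s = f" +/- {err:.3g}" if err is not None and np.isfinite(err) else ""
            lines.append(f"{name:<34}{value:>14.6g}  free{err_s}")
        for name, value in self.fixed.items():
            lines.append(f"{name:<34}{value:>14.6g}  fixed")
        lines += [
            "-" * 58,
            f"chi^2 = {self.chi2:.6g}   dof = {self.dof}   "
            f"chi^2/dof = {self.reduced_chi2:.6g}",
            f"converged = {self.success}   ({self.message})",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "stderr": {k: (None if v is None or not np.isfinite(v) else float(v))
                       for k, v in self.stderr.items()},
            "fixed": dict(self.fixed),
            "chi2": self.chi2,
            "dof": self.dof,
            "reduced_chi2": self.reduced_chi2,
            "success": bool(self.success),
            "message": self.message,
            "nfev": int(self.nfev),
        }

    def plot(self, curve: ScatteringCurve, ax=None, kratky: bool = False):
        """Overlay data and best-fit model (optionally in Kratky form)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve.plot(ax=ax, kratky=kratky, fmt=".", alpha=0.6)
        fit_curve = self.model.evaluate(curve.q)
        if kratky:
            fit_curve = fit_curve.kratky()
        ax.plot(fit_curve.q, fit_curve.I, "-", label="fit")
        ax.legend()
        return ax


@dataclass
class FitProblem:
    """A curve, a composite model, and free/fixed parameter declarations.

    ``free`` maps parameter paths (see :meth:`CompositeModel.get_param`)
    to ``(start, lower, upper)``; ``fixed`` maps paths to pinned values.
    ``q_window`` restricts the fit range.
    """

    curve: ScatteringCurve
    model: CompositeModel
    free: dict
    fixed: dict = field(default_factory=dict)
    q_window: tuple | None = None

    def __post_init__(self):
        for path, spec in self.free.items():
            start, lo, hi = spec
            if not lo < hi:
                raise ValueError(f"{path}: bounds must satisfy lower < upper")
            if not lo <= start <= hi:
                raise ValueError(f"{path}: start value outside bounds")
            self.model.get_param(path)  # raises if the path does not resolve
        for path in self.fixed:
            self.model.get_param(path)

    # ------------------------------------------------------------------
    def _window_curve(self) -> ScatteringCurve:
        curve = self.curve
        if self.q_window is not None:
            curve = crop_q(curve, *self.q_window)
        if curve.sigma is None:
            warnings.warn("curve has no uncertainties; using unit weights")
            return ScatteringCurve(q=curve.q, I=curve.I,
                                   sigma=np.ones_like(curve.I),
                                   label=curve.label)
        good = curve.sigma > 0
        if not np.all(good):
            warnings.warn(
                f"excluding {int(np.sum(~good))} point(s) with sigma = 0")
            curve = ScatteringCurve(q=curve.q[good], I=curve.I[good],
                                    sigma=curve.sigma[good], label=curve.label)
        return curve

    def fit(self, seed: int = 0, n_starts: int = 1,
            max_nfev: int | None = None) -> FitResult:
        """Minimize the weighted chi-square; deterministic given seed.

        Non-convergence is reported in the result flag/message, never
        raised; the best iterate found is always returned, and the
        returned chi-square never exceeds the value at the start point.
        """
        curve = self._window_curve()
        names = list(self.free.keys())
        if len(curve) < len(names) + 1:
            raise ValueError("fewer data points than free parameters + 1")

        model = copy.deepcopy(self.model)
        for path, value in self.fixed.items():
            model.set_param(path, float(value))

        starts = np.array([self.free[n][0] for n in names], dtype=float)
        lo = np.array([self.free[n][1] for n in names], dtype=float)
        hi = np.array([self.free[n][2] for n in names], dtype=float)
        use_log = lo > 0  # positive-bounded parameters fitted in log space
        # centre the log transform on the declared start so the start point
        # round-trips exactly (exp(log(x)) loses an ulp otherwise, which
        # noiseless synthetic curves with epsilon-floor sigmas amplify)
        ref = np.where(use_log, starts, 1.0)

        def to_internal(x):
            return np.where(use_log, np.log(x / ref), x)

        def to_linear(z):
            return np.where(use_log, ref * np.exp(z), z)

        def residuals(z):
            x = to_linear(z)
            for name, value in zip(names, x):
                model.set_param(name, float(value))
            I_model = model.evaluate(curve.q).I
            return (I_model - curve.I) / curve.sigma

        z_lo, z_hi = to_internal(lo), to_internal(hi)
        start_list = [starts]
        if n_starts > 1:
            rng = np.random.default_rng(seed)
            for _ in range(n_starts - 1):
                start_list.append(rng.uniform(lo, hi))

        best = None
        for x0 in start_list:
            sol = least_squares(
                residuals, to_internal(x0), bounds=(z_lo, z_hi),
                method="trf", diff_step=1e-6, max_nfev=max_nfev)
            if best is None or sol.cost < best.cost:
                best = sol

        start_cost = 0.5 * float(np.sum(residuals(to_internal(starts)) ** 2))
        if best.cost > start_cost:  # descent guarantee
            logger.warning("optimizer ended above the start point; "
                           "returning the start values")
            r0 = residuals(to_internal(starts))
            x_best = starts
            res_best = r0
            success, message = False, "no descent from start point"
            jac = None
            nfev = best.nfev
        else:
            x_best = to_linear(best.x)
            res_best = best.fun
            success, message = bool(best.success), str(best.message)
            jac = best.jac
            nfev = best.nfev

        for name, value in zip(names, x_best):
            model.set_param(name, float(value))
        chi2_val = float(np.dot(res_best, res_best))
        dof = max(len(curve) - len(names), 1)

        stderr = {n: None for n in names}
        if jac is not None and jac.size:
            try:
                jtj = jac.T @ jac
                cov = np.linalg.pinv(jtj) * chi2_val / dof
                err_internal = np.sqrt(np.clip(np.diag(cov), 0.0, None))
                # d(linear)/d(log) = value for log-space parameters
                err_linear = np.where(use_log, err_internal * x_best, err_internal)
                stderr = {n: float(e) for n, e in zip(names, err_linear)}
            except np.linalg.LinAlgError:
                pass

        return FitResult(
            params={n: float(v) for n, v in zip(names, x_best)},
            stderr=stderr,
            fixed={k: float(v) for k, v in self.fixed.items()},
            chi2=chi2_val,
            dof=dof,
            residuals=np.asarray(res_best),
            success=success,
            message=message,
            nfev=int(nfev),
            model=model,
            start={n: float(v) for n, v in zip(names, starts)},
        )


def fit(problem: FitProblem, seed: int = 0, **kwargs) -> FitResult:
    """Functional alias for :meth:`FitProblem.fit`."""
    return problem.fit(seed=seed, **kwargs)
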