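"""Equilibrium binding models and dissociation-constant estimation.

Titration plateaus from biolayer interferometry report the fractional
occupancy of an immobilized receptor (here DNA-bound Cra) as a titrant
(FruK) is varied.  When the immobilized concentration ``DT`` is far below
the dissociation constant, the free-titrant approximation holds and the
signal follows a simple hyperbola (:func:`eq1_signal`).  When ``DT`` is
comparable to or above ``Kd`` the titrant is depleted by binding and the
quadratic (Morrison-type) solution of the mass-balance equations must be
used instead (:func:`eq2_signal`).  Because the depleting model carries a
per-experiment ``DT``, a reliable ``Kd`` requires fitting several
titrations simultaneously with the dissociation constant shared across
curves and every other parameter free per curve
(:class:`GlobalBindingFit`).

Concentrations are molar throughout; the independent variable ``x`` is
log10 of the titrant concentration, which equalizes point weighting across
the decades a titration spans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "TitrationCurve",
    "RegimeLabel",
    "FitError",
    "eq1_signal",
    "eq2_signal",
    "classify_regime",
    "BindingCurveFit",
    "GlobalBindingFit",
    "fit_single_curve",
    "fit_global",
    "bootstrap_ci",
]


class FitError(RuntimeError):
    """Raised when no optimizer start converges; carries the best attempt."""

    def __init__(self, message: str, best_result=None):
        super().__init__(message)
        self.best_result = best_result


@dataclass(frozen=True)
class TitrationCurve:
    """One equilibrium titration: plateau signal versus log10 titrant (M).

    Parameters
    ----------
    curve_id:
        Label for the experiment the curve came from.
    x:
        log10 of titrant concentration in molar units.
    y:
        Observed plateau signal (instrument units).
    dt_hint:
        Optional prior estimate of the fixed-component (immobilized
        receptor) concentration in M, used to start the depleting fit.
    """

    curve_id: str
    x: np.ndarray
    y: np.ndarray
    dt_hint: float | None = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.shape != x.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size < 4:
            raise ValueError(f"curve {self.curve_id!r}: needs >= 4 points, got {x.size}")
        if not np.all(np.isfinite(x)):
            raise ValueError(f"curve {self.curve_id!r}: x contains non-finite values")
        if np.unique(x).size < 2:
            raise ValueError(f"curve {self.curve_id!r}: needs >= 2 distinct x values")
        if self.dt_hint is not None and self.dt_hint <= 0:
            raise ValueError(f"curve {self.curve_id!r}: dt_hint must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> list["TitrationCurve"]:
        """Build curves from a tidy table with columns curve_id, conc_M, signal."""
        out = []
        for cid, grp in df.groupby("curve_id", sort=True):
            hint = None
            if "DT_hint_M" in grp.columns and grp["DT_hint_M"].notna().any():
                hint = float(grp["DT_hint_M"].dropna().iloc[0])
            out.append(
                cls(
                    curve_id=str(cid),
                    x=np.log10(grp["conc_M"].to_numpy(dtype=float)),
                    y=grp["signal"].to_numpy(dtype=float),
                    dt_hint=hint,
                )
            )
        return out


@dataclass(frozen=True)
class RegimeLabel:
    """Binding-regime classification by the ratio DT / Kd."""

    label: Literal["equilibrium", "intermediate", "stoichiometric"]
    ratio: float


def eq1_signal(x, kd: float, c: float = 0.0, ymax: float = 1.0):
    """Hyperbolic (non-depleting) binding signal.

    ``Y = c + Ymax * 10**x / (Kd + 10**x)`` with ``x = log10([titrant]/M)``.
    Valid only when the fixed component is well below ``Kd``.
    """
    if kd <= 0:
        raise ValueError("Kd must be positive")
    ell = np.power(10.0, np.asarray(x, dtype=float))
    return c + ymax * ell / (kd + ell)


def eq2_signal(x, kd: float, dt: float, c: float = 0.0, ymax: float = 1.0, n: float = 1.0):
    """Quadratic ligand-depletion binding signal.

    Solves the mass balance for a fixed component at total concentration
    ``dt`` binding ``n`` titrant molecules with dissociation constant
    ``kd``.  With ``L = 10**x`` and ``a = n + L/DT + Kd/DT``::

        Y = c + Ymax * (a - sqrt(a**2 - 4*n*L/DT)) / (2*n)

    The discriminant is mathematically nonnegative; round-off can push it
    slightly below zero, so it is clamped at zero.
    """
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if dt <= 0:
        raise ValueError("DT must be positive")
    if n <= 0:
        raise ValueError("n must be positive")
    ell = np.power(10.0, np.asarray(x, dtype=float))
    a = n + ell / dt + kd / dt
    disc = np.clip(a * a - 4.0 * n * ell / dt, 0.0, None)
    return c + ymax * (a - np.sqrt(disc)) / (2.0 * n)


def classify_regime(dt: float, kd: float) -> RegimeLabel:
    """Classify a binding assay by the ratio of fixed component to Kd.

    ``DT <= Kd/10`` is the equilibrium regime (the hyperbolic model is
    valid), ``DT >= 10*Kd`` is the stoichiometric regime, anything between
    is intermediate.  Boundary ratios are assigned to the outer regimes.
    """
    if dt <= 0 or kd <= 0:
        raise ValueError("DT and Kd must be positive")
    ratio = dt / kd
    if ratio <= 0.1:
        return RegimeLabel("equilibrium", ratio)
    if ratio >= 10.0:
        return RegimeLabel("stoichiometric", ratio)
    return RegimeLabel("intermediate", ratio)


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of rows")
    return X, y


class BindingCurveFit(RegressorMixin, BaseEstimator):
    """Weighted least-squares fit of a single titration curve.

    ``Kd`` (and ``DT`` when free) are optimized on a log10 scale, which
    enforces positivity and matches the decade-spanning design of a
    titration.  A multistart over log-spaced ``Kd`` values guards against
    the flat-valley local minima typical of these models.

    Parameters
    ----------
    model:
        "eq1" for the hyperbolic model, "eq2" for the ligand-depletion
        model (requires ``dt``).
    dt:
        Fixed-component concentration (M) for eq2.  Used as the fixed
        value when ``fix_dt`` is True, else as the starting value.
    fix_dt:
        Whether ``dt`` is held fixed (default) or optimized.
    n:
        Binding stoichiometry, held fixed (default 1).
    kd_bounds:
        Multistart/search range for Kd in molar units.
    n_starts:
        Number of log-spaced Kd starting values.

    Attributes
    ----------
    kd_, c_, ymax_, dt_ : fitted parameters.
    kd_se_ : asymptotic standard error of Kd (M), from the Jacobian.
    rss_ : residual sum of squares at the optimum.
    converged_ : whether the best start reported success.
    identifiable_ : False when the data span less than 20% of the fitted
        amplitude, i.e. the plateau was never approached.
    """

    def __init__(
        self,
        model: Literal["eq1", "eq2"] = "eq1",
        dt: float | None = None,
        fix_dt: bool = True,
        n: float = 1.0,
        kd_bounds: tuple[float, float] = (1e-12, 1e-5),
        n_starts: int = 7,
    ):
        self.model = model
        self.dt = dt
        self.fix_dt = fix_dt
        self.n = n
        self.kd_bounds = kd_bounds
        self.n_starts = n_starts

    def _signal(self, x, log_kd, c, ymax, log_dt=None):
        kd = 10.0 ** log_kd
        if self.model == "eq1":
            return eq1_signal(x, kd, c, ymax)
        return eq2_signal(x, kd, 10.0 ** log_dt, c, ymax, self.n)

    def fit(self, X, y, sample_weight=None):
        if self.model not in ("eq1", "eq2"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "eq2" and self.dt is None:
            raise ValueError("eq2 requires dt (fixed-component concentration)")
        X, y = _validate_xy(X, y)
        if X.shape[0] < 4:
            raise ValueError("need >= 4 points to fit a titration curve")
        x = X[:, 0]
        w = np.ones_like(y) if sample_weight is None else np.sqrt(np.asarray(sample_weight, float))

        free_dt = self.model == "eq2" and not self.fix_dt
        lo_kd, hi_kd = np.log10(self.kd_bounds[0]), np.log10(self.kd_bounds[1])
        c0 = float(np.min(y))
        span = float(np.max(y) - np.min(y))
        ymax0 = span if span > 0 else 1.0
        log_dt0 = np.log10(self.dt) if self.dt is not None else -9.0

        def resid(theta):
            if free_dt:
                log_kd, c, ymax, log_dt = theta
            else:
                log_kd, c, ymax = theta
                log_dt = np.log10(self.dt) if self.dt is not None else None
            return w * (self._signal(x, log_kd, c, ymax, log_dt) - y)

        lower = [lo_kd, -np.inf, -np.inf]
        upper = [hi_kd, np.inf, np.inf]
        if free_dt:
            lower.append(-14.0)
            upper.append(-4.0)

        best = None
        for log_kd0 in np.linspace(lo_kd, hi_kd, self.n_starts):
            theta0 = [log_kd0, c0, ymax0] + ([log_dt0] if free_dt else [])
            try:
                res = least_squares(resid, theta0, bounds=(lower, upper), method="trf")
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise FitError("all multistart attempts failed")

        theta = best.x
        self.kd_ = float(10.0 ** theta[0])
        self.c_ = float(theta[1])
        self.ymax_ = float(theta[2])
        self.dt_ = float(10.0 ** theta[3]) if free_dt else self.dt
        self.rss_ = float(2.0 * best.cost)
        self.converged_ = bool(best.success)
        self.kd_se_ = _se_from_jac(best, index=0) * self.kd_ * np.log(10.0)
        data_span = float(np.max(y) - np.min(y))
        self.identifiable_ = (
            abs(self.ymax_) > 1e-12 * max(1.0, float(np.max(np.abs(y))))
            and data_span >= 0.2 * abs(self.ymax_)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "kd_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        log_dt = None if self.model == "eq1" else np.log10(self.dt_)
        return self._signal(X[:, 0], np.log10(self.kd_), self.c_, self.ymax_, log_dt)


def _se_from_jac(res, index: int) -> float:
    """Asymptotic SE of one parameter from a least_squares result."""
    m, p = res.jac.shape
    dof = max(m - p, 1)
    s2 = 2.0 * res.cost / dof
    try:
        jtj = res.jac.T @ res.jac
        cov = s2 * np.linalg.pinv(jtj)
        var = cov[index, index]
        return float(np.sqrt(var)) if var > 0 else float("nan")
    except np.linalg.LinAlgError:
        return float("nan")


class GlobalBindingFit(BaseEstimator):
    """Global depleting-model fit with one shared dissociation constant.

    All curves share a single ``Kd``; each curve keeps its own baseline
    ``c``, amplitude ``Ymax`` and effective fixed-component concentration
    ``DT``.  The per-curve ``DT`` replaces the manual vary-and-refit
    iteration of the bench protocol with one joint optimization of the
    same pooled objective.

    Data layout: ``X`` has two columns, ``X[:, 0]`` an integer curve index
    and ``X[:, 1]`` the log10 titrant concentration (M); ``y`` is the
    signal.  :meth:`from_curves` converts a list of
    :class:`TitrationCurve` into this layout.

    Attributes
    ----------
    kd_ : shared dissociation constant (M).
    kd_se_ : asymptotic standard error of ``kd_`` (M).
    per_curve_ : DataFrame with per-curve c, Ymax, DT, RSS and regime.
    rss_ : pooled residual sum of squares.
    converged_ : optimizer success flag for the winning start.
    """

    model_ = "eq2"

    def __init__(
        self,
        n: float = 1.0,
        dt_init: float = 1e-9,
        kd_bounds: tuple[float, float] = (1e-12, 1e-5),
        n_starts: int = 7,
    ):
        self.n = n
        self.dt_init = dt_init
        self.kd_bounds = kd_bounds
        self.n_starts = n_starts

    @staticmethod
    def from_curves(curves: Sequence[TitrationCurve]):
        """Stack curves into the (X, y, dt_hints) layout used by fit."""
        idx = np.concatenate([np.full(c.x.size, i, dtype=float) for i, c in enumerate(curves)])
        x = np.concatenate([c.x for c in curves])
        y = np.concatenate([c.y for c in curves])
        hints = [c.dt_hint for c in curves]
        return np.column_stack([idx, x]), y, hints

    def _unpack(self, theta, n_curves):
        log_kd = theta[0]
        per = theta[1:].reshape(n_curves, 3)  # columns: c, ymax, log_dt
        return log_kd, per

    def _model_y(self, theta, idx, x, n_curves):
        log_kd, per = self._unpack(theta, n_curves)
        kd = 10.0 ** log_kd
        c = per[idx, 0]
        ymax = per[idx, 1]
        dt = 10.0 ** per[idx, 2]
        ell = 10.0 ** x
        a = self.n + ell / dt + kd / dt
        disc = np.clip(a * a - 4.0 * self.n * ell / dt, 0.0, None)
        return c + ymax * (a - np.sqrt(disc)) / (2.0 * self.n)

    def fit(self, X, y, sample_weight=None, dt_hints=None):
        X, y = _validate_xy(X, y)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: curve index, log10 concentration")
        idx_raw = X[:, 0]
        x = X[:, 1]
        labels, idx = np.unique(idx_raw, return_inverse=True)
        n_curves = labels.size
        if n_curves < 2:
            raise ValueError("global fitting requires >= 2 curves")
        for i in range(n_curves):
            m = idx == i
            if m.sum() < 4 or np.unique(x[m]).size < 2:
                raise ValueError(f"curve {labels[i]}: needs >= 4 points and >= 2 distinct x")
        w = np.ones_like(y) if sample_weight is None else np.sqrt(np.asarray(sample_weight, float))

        lo_kd, hi_kd = np.log10(self.kd_bounds[0]), np.log10(self.kd_bounds[1])
        hints = list(dt_hints) if dt_hints is not None else [None] * n_curves
        per0 = np.empty((n_curves, 3))
        for i in range(n_curves):
            yi = y[idx == i]
            span = float(yi.max() - yi.min())
            dt0 = hints[i] if hints[i] else self.dt_init
            per0[i] = [yi.min(), span if span > 0 else 1.0, np.log10(dt0)]

        lower = np.concatenate([[lo_kd], np.tile([-np.inf, -np.inf, -14.0], n_curves)])
        upper = np.concatenate([[hi_kd], np.tile([np.inf, np.inf, -4.0], n_curves)])

        def resid(theta):
            return w * (self._model_y(theta, idx, x, n_curves) - y)

        best = None
        for log_kd0 in np.linspace(lo_kd, hi_kd, self.n_starts):
            theta0 = np.concatenate([[log_kd0], per0.ravel()])
            try:
                res = least_squares(resid, theta0, bounds=(lower, upper), method="trf")
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise FitError("all multistart attempts failed")

        log_kd, per = self._unpack(best.x, n_curves)
        self.kd_ = float(10.0 ** log_kd)
        self.kd_se_ = _se_from_jac(best, index=0) * self.kd_ * np.log(10.0)
        self.rss_ = float(2.0 * best.cost)
        self.converged_ = bool(best.success)
        self.n_curves_ = n_curves
        self._labels = labels
        self._theta = best.x.copy()
        rows = []
        for i in range(n_curves):
            m = idx == i
            r = eq2_signal(x[m], self.kd_, 10.0 ** per[i, 2], per[i, 0], per[i, 1], self.n) - y[m]
            dt_i = float(10.0 ** per[i, 2])
            rows.append(
                {
                    "curve": labels[i],
                    "c": float(per[i, 0]),
                    "ymax": float(per[i, 1]),
                    "dt_M": dt_i,
                    "rss": float(np.sum(r * r)),
                    "n_points": int(m.sum()),
                    "regime": classify_regime(dt_i, self.kd_).label,
                }
            )
        self.per_curve_ = pd.DataFrame(rows)
        return self

    def predict(self, X):
        check_is_fitted(self, "kd_")
        X = np.asarray(X, dtype=float)
        idx = np.searchsorted(self._labels, X[:, 0])
        return self._model_y(self._theta, idx, X[:, 1], self.n_curves_)

    def bootstrap_kd_ci(self, X, y, n_boot: int = 200, seed: int = 0, alpha: float = 0.05):
        """Parametric-bootstrap confidence interval for the shared Kd.

        Residual SDs are estimated per curve from the fit, Gaussian noise
        at those SDs is re-simulated on the fitted curves, and the global
        fit is repeated (warm-started at the fitted optimum) for each
        replicate.  Returns ``(lo, hi, kd_samples)`` with the percentile
        interval at level ``1 - alpha``.
        """
        check_is_fitted(self, "kd_")
        if n_boot < 50:
            warnings.warn(f"n_boot={n_boot} < 50: interval will be unstable", stacklevel=2)
        X, y = _validate_xy(X, y)
        idx = np.searchsorted(self._labels, X[:, 0])
        x = X[:, 1]
        fitted = self._model_y(self._theta, idx, x, self.n_curves_)
        sd = np.empty_like(y)
        for i in range(self.n_curves_):
            m = idx == i
            resid_i = y[m] - fitted[m]
            dof = max(int(m.sum()) - 3, 1)
            sd[m] = np.sqrt(np.sum(resid_i * resid_i) / dof)

        lo_kd, hi_kd = np.log10(self.kd_bounds[0]), np.log10(self.kd_bounds[1])
        lower = np.concatenate([[lo_kd], np.tile([-np.inf, -np.inf, -14.0], self.n_curves_)])
        upper = np.concatenate([[hi_kd], np.tile([np.inf, np.inf, -4.0], self.n_curves_)])
        rng = np.random.default_rng(seed)
        samples = np.empty(n_boot)
        for b in range(n_boot):
            yb = fitted + rng.normal(0.0, sd)

            def resid(theta):
                return self._model_y(theta, idx, x, self.n_curves_) - yb

            res = least_squares(resid, self._theta, bounds=(lower, upper), method="trf")
            samples[b] = 10.0 ** res.x[0]
        lo = float(np.quantile(samples, alpha / 2))
        hi = float(np.quantile(samples, 1 - alpha / 2))
        return lo, hi, samples


def fit_single_curve(
    curve: TitrationCurve,
    model: Literal["eq1", "eq2"] = "eq1",
    fixed: dict | None = None,
) -> BindingCurveFit:
    """Fit one titration curve; ``fixed`` may pin ``n`` and/or ``DT``."""
    fixed = fixed or {}
    dt = fixed.get("DT", curve.dt_hint)
    est = BindingCurveFit(
        model=model,
        dt=dt,
        fix_dt="DT" in fixed,
        n=fixed.get("n", 1.0),
    )
    if model == "eq2" and dt is None:
        est.set_params(dt=1e-9, fix_dt=False)
    return est.fit(curve.x[:, None], curve.y)


def fit_global(curves: Sequence[TitrationCurve], n: float = 1.0, **kwargs) -> GlobalBindingFit:
    """Global shared-Kd fit of several titration curves (depleting model)."""
    X, y, hints = GlobalBindingFit.from_curves(curves)
    return GlobalBindingFit(n=n, **kwargs).fit(X, y, dt_hints=hints)


def bootstrap_ci(
    fit: GlobalBindingFit,
    curves: Sequence[TitrationCurve],
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Percentile bootstrap interval for the shared Kd of a global fit."""
    X, y, _ = GlobalBindingFit.from_curves(curves)
    return fit.bootstrap_kd_ci(X, y, n_boot=n_boot, seed=seed, alpha=alpha)
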