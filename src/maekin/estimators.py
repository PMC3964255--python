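"""Scikit-learn style estimators for extraction-kinetics curve fitting.

Each estimator solves an unweighted nonlinear least-squares problem with the
Levenberg-Marquardt algorithm (:func:`scipy.optimize.least_squares`,
``method="lm"``).  Positive parameters (``y_max``, ``k_m``, ``ref``) are
log-reparameterized so the optimizer can roam freely without proposing
negative rates; the delay ``tau`` is left untransformed.

The estimators follow the scikit-learn contract: hyperparameters in
``__init__``, data only in ``fit(X, y)``, fitted attributes with a trailing
underscore, and ``predict(X)`` for the forward model — so they compose with
pipelines and model selection.  ``X`` is the time column for the per-curve
models, and a two-column ``(time, design value)`` array for the generalized
model.

Goodness of fit is reported as the dimensionless ratio of the
root-mean-square residual to the model's asymptotic (limit) yield.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize
from scipy.special import expit
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .models import separable_power_logistic

__all__ = [
    "FirstOrderExtraction",
    "DelayedLogisticExtraction",
    "GlobalLogisticExtraction",
    "DegenerateDataError",
    "heuristic_start",
]


class DegenerateDataError(ValueError):
    """Raised when a curve carries no usable signal (e.g. all-zero yields)."""


def _validate_curve(X, y, n_params: int, n_cols: int = 1):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[1] != n_cols:
        raise ValueError(f"X must have {n_cols} column(s), got shape {X.shape}")
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(X):
        raise ValueError("X and y must have the same number of samples")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("X and y must be finite")
    if np.any(X[:, 0] < 0):
        raise ValueError("extraction times must be >= 0")
    if np.any(y < 0):
        raise ValueError("yields must be >= 0")
    if len(y) < n_params:
        raise ValueError(
            f"at least {n_params} points are required for a {n_params}-parameter fit,"
            f" got {len(y)}"
        )
    return X, y


def heuristic_start(times, yields, model: str):
    """Data-driven starting values for the kinetic fits.

    The asymptote starts at the maximum observed yield; the rate at
    ``3 / t95`` where ``t95`` is the first time the yield exceeds 95% of its
    plateau (falling back to ``3 / median(times)`` when that time is zero);
    and, for the logistic model, the delay at the first time the yield
    exceeds half its plateau.

    Parameters
    ----------
    times, yields : array_like
        The observed curve; yields all zero raise :class:`DegenerateDataError`.
    model : {"first_order", "logistic"}

    Returns
    -------
    tuple of float
        ``(y_max0, k_m0)`` or ``(y_max0, k_m0, tau0)``.
    """
    times = np.asarray(times, dtype=float)
    yields = np.asarray(yields, dtype=float)
    plateau = float(np.max(yields))
    if plateau <= 0:
        raise DegenerateDataError("all-zero yield curve: nothing to fit")
    y_max0 = plateau
    above95 = times[yields > 0.95 * plateau]
    t95 = float(above95[0]) if above95.size else float(np.median(times))
    if t95 <= 0:
        t95 = float(np.median(times))
    if t95 <= 0:
        raise DegenerateDataError("cannot form a rate guess from a zero time grid")
    k_m0 = 3.0 / t95
    if model == "first_order":
        return y_max0, k_m0
    above_half = times[yields > 0.5 * plateau]
    tau0 = float(above_half[0]) if above_half.size else float(np.median(times))
    return y_max0, k_m0, tau0


class _LMKineticBase(RegressorMixin, BaseEstimator):
    """Shared Levenberg-Marquardt machinery.

    Subclasses define ``_n_params``, the transformed-space residual, the
    heuristic start and the mapping back to natural parameters.
    """

    model_tag: str = ""
    _n_params: int = 0

    def __init__(self, tol=1e-10, max_iter=500, multistart=False, n_starts=8,
                 random_state=None):
        self.tol = tol
        self.max_iter = max_iter
        self.multistart = multistart
        self.n_starts = n_starts
        self.random_state = random_state

    # subclass hooks -----------------------------------------------------
    def _start(self, X, y):
        raise NotImplementedError

    def _residuals(self, z, X, y):
        raise NotImplementedError

    def _unpack(self, z):
        """Transformed vector -> dict of natural parameters."""
        raise NotImplementedError

    def _start_spread(self, z0, X):
        """Half-widths of the multistart box around ``z0``."""
        raise NotImplementedError

    # fitting ------------------------------------------------------------
    def _solve_from(self, z0, X, y):
        return optimize.least_squares(
            self._residuals, z0, args=(X, y), method="lm",
            ftol=self.tol, xtol=self.tol, gtol=self.tol,
            max_nfev=self.max_iter * (len(z0) + 1),
        )

    def _fit_transformed(self, X, y):
        z0 = self._start(X, y)
        result = self._solve_from(z0, X, y)
        if self.multistart:
            rng = np.random.default_rng(self.random_state)
            sampler = qmc.LatinHypercube(d=len(z0), seed=rng)
            spread = self._start_spread(z0, X)
            unit = sampler.random(self.n_starts)
            candidates = [result]
            for row in unit:
                zi = np.asarray(z0) + (2.0 * row - 1.0) * spread
                candidates.append(self._solve_from(zi, X, y))
            best = min(c.cost for c in candidates)
            # ties broken by the smallest rate constant
            near = [c for c in candidates if c.cost <= best * (1 + 1e-12) + 1e-300]
            result = min(near, key=lambda c: self._unpack(c.x)["k_m"])
        return result

    def _finalize(self, result, X, y):
        params = self._unpack(result.x)
        for name, value in params.items():
            setattr(self, name + "_", float(value))
        n, p = len(y), self._n_params  # includes any profiled amplitude
        resid = result.fun
        self.residuals_ = -resid  # observed minus fitted
        self.rms_ = float(np.sqrt(np.mean(resid ** 2)))
        self.n_iter_ = int(result.nfev)
        self.converged_ = bool(result.status > 0)
        if not self.converged_:
            warnings.warn(
                f"{type(self).__name__}: Levenberg-Marquardt did not converge "
                f"within {self.max_iter} iterations", RuntimeWarning)
        # parameter covariance from the Jacobian at the optimum, mapped from
        # the log-transformed space to natural units by the delta method
        J = result.jac
        JtJ = J.T @ J
        dof = n - p
        s2 = 2.0 * result.cost / dof if dof > 0 else np.nan
        rank = np.linalg.matrix_rank(JtJ)
        self.jacobian_singular_ = bool(rank < len(result.x))
        cov_z = s2 * np.linalg.pinv(JtJ)
        D = np.diag(self._natural_gradient(result.x))
        self.covariance_ = D @ cov_z @ D
        self.n_features_in_ = X.shape[1]
        return self

    def _natural_gradient(self, z):
        """d(natural)/d(transformed) on the diagonal, for the delta method."""
        raise NotImplementedError


class FirstOrderExtraction(_LMKineticBase):
    """Pseudo-first-order extraction model ``y_max * (1 - exp(-k_m * t))``.

    Parameters
    ----------
    tol : float, default=1e-10
        Gradient, step and objective tolerance of the optimizer.
    max_iter : int, default=500
        Iteration budget.
    multistart : bool, default=False
        Add a seeded 8-point Latin-hypercube multistart around the heuristic
        start; the best objective wins, ties broken by smallest ``k_m``.
    n_starts : int, default=8
    random_state : int or None
        Seed for the multistart sampler.

    Attributes
    ----------
    y_max_ : float
        Fitted asymptotic yield, mg/g.
    k_m_ : float
        Fitted rate constant, 1/s.
    rms_ : float
        Root-mean-square residual, mg/g.
    gof_ : float
        ``rms_ / y_max_`` — dimensionless goodness-of-fit indicator.
    converged_ : bool
    n_iter_ : int
    covariance_ : ndarray of shape (2, 2)
        Parameter covariance in natural units (y_max, k_m).
    """

    model_tag = "first_order"
    _n_params = 2

    def _start(self, X, y):
        y_max0, k_m0 = heuristic_start(X[:, 0], y, "first_order")
        return np.array([np.log(y_max0), np.log(k_m0)])

    def _residuals(self, z, X, y):
        y_max, k_m = np.exp(z)
        return y_max * -np.expm1(-k_m * X[:, 0]) - y

    def _unpack(self, z):
        return {"y_max": np.exp(z[0]), "k_m": np.exp(z[1])}

    def _natural_gradient(self, z):
        return np.exp(z)

    def _start_spread(self, z0, X):
        return np.array([np.log(10.0), np.log(10.0)])

    def fit(self, X, y):
        """Fit the model to a yield curve.

        Parameters
        ----------
        X : array_like of shape (n,) or (n, 1)
            Extraction times, s.
        y : array_like of shape (n,)
            Yields, mg/g.  At least 2 points; at least one nonzero.
        """
        X, y = _validate_curve(X, y, self._n_params)
        result = self._fit_transformed(X, y)
        self._finalize(result, X, y)
        self.gof_ = self.rms_ / self.y_max_ if self.y_max_ > 0 else np.inf
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        t = X[:, 0] if X.ndim == 2 else X
        return self.y_max_ * -np.expm1(-self.k_m_ * t)


class DelayedLogisticExtraction(_LMKineticBase):
    """Delayed logistic model ``y_max / (1 + exp(-k_m * (t - tau)))``.

    Same hyperparameters as :class:`FirstOrderExtraction`; the extra fitted
    attribute ``tau_`` is the time delay in seconds (negative values are
    tolerated but indicate a degenerate fit).
    """

    model_tag = "logistic"
    _n_params = 3

    def _start(self, X, y):
        y_max0, k_m0, tau0 = heuristic_start(X[:, 0], y, "logistic")
        return np.array([np.log(y_max0), np.log(k_m0), tau0])

    def _residuals(self, z, X, y):
        y_max, k_m = np.exp(z[:2])
        return y_max * expit(k_m * (X[:, 0] - z[2])) - y

    def _unpack(self, z):
        return {"y_max": np.exp(z[0]), "k_m": np.exp(z[1]), "tau": z[2]}

    def _natural_gradient(self, z):
        return np.array([np.exp(z[0]), np.exp(z[1]), 1.0])

    def _start_spread(self, z0, X):
        t = X[:, 0]
        return np.array([np.log(10.0), np.log(10.0), (t[-1] - t[0]) / 4.0])

    def fit(self, X, y):
        """Fit the delayed logistic to a yield curve (>= 3 points)."""
        X, y = _validate_curve(X, y, self._n_params)
        result = self._fit_transformed(X, y)
        self._finalize(result, X, y)
        self.gof_ = self.rms_ / self.y_max_ if self.y_max_ > 0 else np.inf
        if self.tau_ < 0:
            warnings.warn("fitted delay tau is negative (degenerate fit)",
                          RuntimeWarning)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        t = X[:, 0] if X.ndim == 2 else X
        return self.y_max_ * expit(self.k_m_ * (t - self.tau_))


class GlobalLogisticExtraction(_LMKineticBase):
    """Design-variable-dependent logistic model, fitted by variable projection.

    The surface ``A * f(t, x; ref, k_m, tau)`` with the separable strategy
    ``f = (1 - exp(-x/ref)) / (1 + exp(-k_m (t - tau)))`` is fitted jointly
    over a family of curves.  The linear amplitude ``A`` is profiled out at
    every nonlinear iteration by exact linear least squares, so the optimizer
    only sees the nonlinear parameters ``(ref, k_m, tau)``.

    Parameters
    ----------
    strategy : callable, default separable saturation-times-logistic
        Unit-amplitude surface ``f(t, x, ref, k_m, tau)``; swap it to revisit
        the functional form without touching the fitting machinery.
    fix_ref : float or None
        When set, ``ref`` is held at this value and only ``(k_m, tau)`` are
        optimized (the amplitude is still profiled).
    tol, max_iter, multistart, n_starts, random_state
        As in :class:`FirstOrderExtraction`.

    Attributes
    ----------
    ref_, k_m_, tau_, amplitude_ : float
        Fitted parameters (amplitude recovered by the closed-form projection
        at the optimum).
    rms_ : float
        Pooled root-mean-square residual, mg/g.
    gof_ : float
        Pooled rms over the maximum fitted yield across all cells.
    """

    model_tag = "global"

    def __init__(self, strategy=separable_power_logistic, fix_ref=None,
                 tol=1e-10, max_iter=500, multistart=False, n_starts=8,
                 random_state=None):
        super().__init__(tol=tol, max_iter=max_iter, multistart=multistart,
                         n_starts=n_starts, random_state=random_state)
        self.strategy = strategy
        self.fix_ref = fix_ref

    @property
    def _n_params(self):  # nonlinear + profiled amplitude
        return (2 if self.fix_ref is not None else 3) + 1

    def _theta(self, z):
        if self.fix_ref is not None:
            return float(self.fix_ref), np.exp(z[0]), z[1]
        return np.exp(z[0]), np.exp(z[1]), z[2]

    def _profile_amplitude(self, z, X, y):
        ref, k_m, tau = self._theta(z)
        m = self.strategy(X[:, 0], X[:, 1], ref, k_m, tau)
        mm = float(m @ m)
        amp = max(float(m @ y) / mm, 0.0) if mm > 0 else 0.0
        return amp, m

    def _residuals(self, z, X, y):
        amp, m = self._profile_amplitude(z, X, y)
        return amp * m - y

    def _unpack(self, z):
        ref, k_m, tau = self._theta(z)
        return {"ref": ref, "k_m": k_m, "tau": tau}

    def _natural_gradient(self, z):
        if self.fix_ref is not None:
            return np.array([np.exp(z[0]), 1.0])
        return np.array([np.exp(z[0]), np.exp(z[1]), 1.0])

    def _start(self, X, y):
        t, x = X[:, 0], X[:, 1]
        top = x == np.max(x)
        order = np.argsort(t[top])
        _, k_m0, tau0 = heuristic_start(t[top][order], y[top][order], "logistic")
        if self.fix_ref is not None:
            return np.array([np.log(k_m0), tau0])
        return np.array([np.log(np.median(np.unique(x))), np.log(k_m0), tau0])

    def _start_spread(self, z0, X):
        t = X[:, 0]
        span = (np.max(t) - np.min(t)) / 4.0
        if self.fix_ref is not None:
            return np.array([np.log(10.0), span])
        return np.array([np.log(10.0), np.log(10.0), span])

    def fit(self, X, y):
        """Fit the generalized model.

        Parameters
        ----------
        X : array_like of shape (n, 2)
            Columns ``(time s, design-variable value)``; design values > 0.
        y : array_like of shape (n,)
            Yields, mg/g.
        """
        X, y = _validate_curve(X, y, self._n_params, n_cols=2)
        if np.any(X[:, 1] <= 0):
            raise ValueError("design-variable values must be > 0")
        if float(np.max(y)) <= 0:
            raise DegenerateDataError("all-zero yield family: nothing to fit")
        result = self._fit_transformed(X, y)
        self._finalize(result, X, y)
        amp, m = self._profile_amplitude(result.x, X, y)
        self.amplitude_ = float(amp)
        fitted = amp * m
        self.gof_ = self.rms_ / float(np.max(fitted)) if np.max(fitted) > 0 else np.inf
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        return self.amplitude_ * self.strategy(
            X[:, 0], X[:, 1], self.ref_, self.k_m_, self.tau_)
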