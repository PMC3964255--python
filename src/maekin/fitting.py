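"""Per-curve nonlinear least-squares fitting and the goodness indicator.

Thin functional layer over the estimators in :mod:`maekin.estimators`:
an :class:`ExtractionCurve` goes in, a :class:`KineticFit` record comes out.
The goodness-of-fit indicator is the dimensionless ratio of the
root-mean-square residual to the fitted asymptotic yield (the model
parameter, not the data maximum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .estimators import (DegenerateDataError, DelayedLogisticExtraction,
                         FirstOrderExtraction, GlobalLogisticExtraction,
                         heuristic_start)
from .models import FirstOrderParams, GlobalParams, LogisticParams

__all__ = [
    "ExtractionCurve",
    "KineticFit",
    "initial_guess",
    "fit_curve",
    "gof_ratio",
    "DegenerateDataError",
    "InsufficientDataError",
]

Params = Union[FirstOrderParams, LogisticParams, GlobalParams]

_MIN_POINTS = {"first_order": 4, "logistic": 5}


class InsufficientDataError(ValueError):
    """Raised when a curve has too few points for the requested model."""


@dataclass(frozen=True)
class ExtractionCurve:
    """One yield-vs-time series at a fixed design point.

    Attributes
    ----------
    factor_name : str
        One of ``power``, ``ethanol``, ``preleach``.
    factor_level : float
        Numeric level (W, % v/v or min depending on the factor).
    times : ndarray
        Sampling times, s; strictly increasing, >= 0.
    yields : ndarray
        Mangiferin contents, mg/g; >= 0, same length as ``times``.
    replicate : int or None
        Optional replicate id.
    """

    factor_name: str
    factor_level: float
    times: np.ndarray
    yields: np.ndarray
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        yields = np.asarray(self.yields, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "yields", yields)
        if times.ndim != 1 or yields.ndim != 1 or len(times) != len(yields):
            raise ValueError("times and yields must be 1-D and equally long")
        if len(times) and times[0] < 0:
            raise ValueError("times must be >= 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(yields < 0):
            raise ValueError("yields must be >= 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class KineticFit:
    """Result record of one kinetic model fit.

    ``params`` carries the fitted parameter container; ``rms`` (mg/g) and the
    dimensionless ``gof`` (rms over asymptotic yield) summarize the residuals.
    """

    model_tag: str
    params: Params
    rms: float
    gof: float
    n_iter: int
    converged: bool
    covariance: Optional[np.ndarray] = field(default=None, repr=False)

    def to_record(self) -> dict:
        """Flat JSON-ready record with the canonical field names."""
        p = self.params
        return {
            "model": self.model_tag,
            "y_max": getattr(p, "y_max", None),
            "k_m": p.k_m,
            "tau": getattr(p, "tau", None),
            "ref": getattr(p, "ref", None),
            "amplitude": getattr(p, "amplitude", None),
            "rms": self.rms,
            "gof": self.gof,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def initial_guess(curve: ExtractionCurve, model_tag: str) -> Params:
    """Heuristic starting parameters for a per-curve fit.

    See :func:`maekin.estimators.heuristic_start` for the rules; raises
    :class:`DegenerateDataError` on an all-zero curve.
    """
    vals = heuristic_start(curve.times, curve.yields, model_tag)
    if model_tag == "first_order":
        return FirstOrderParams(*vals)
    if model_tag == "logistic":
        return LogisticParams(*vals)
    raise ValueError(f"unknown model tag {model_tag!r}")


def _estimator_for(model_tag: str, tol: float, max_iter: int,
                   multistart: bool, random_state):
    cls = {"first_order": FirstOrderExtraction,
           "logistic": DelayedLogisticExtraction}.get(model_tag)
    if cls is None:
        raise ValueError(f"unknown model tag {model_tag!r}")
    return cls(tol=tol, max_iter=max_iter, multistart=multistart,
               random_state=random_state)


def fit_curve(curve: ExtractionCurve, model_tag: str = "logistic",
              init: Optional[Params] = None, tol: float = 1e-10,
              max_iter: int = 500, multistart: bool = False,
              random_state=None) -> KineticFit:
    """Levenberg-Marquardt fit of one extraction curve.

    Parameters
    ----------
    curve : ExtractionCurve
    model_tag : {"first_order", "logistic"}
    init : params or None
        Explicit start; by default the data-driven heuristic is used.
    tol : float
        Gradient/step/objective tolerance (default 1e-10).
    max_iter : int
        Iteration budget (default 500); exhaustion yields ``converged=False``,
        never a silent success.
    multistart : bool
        Enable the seeded Latin-hypercube multistart.

    Returns
    -------
    KineticFit

    Raises
    ------
    InsufficientDataError
        Fewer points than the model's minimum (4 for the two-parameter
        model, 5 for the three-parameter one).
    DegenerateDataError
        All-zero yields.
    """
    need = _MIN_POINTS[model_tag] if model_tag in _MIN_POINTS else 4
    if len(curve) < need:
        raise InsufficientDataError(
            f"{model_tag} fit needs >= {need} points, curve has {len(curve)}")
    est = _estimator_for(model_tag, tol, max_iter, multistart, random_state)
    if init is not None:
        # route an explicit start through the estimator's transformed space
        if model_tag == "first_order":
            z0 = np.array([np.log(init.y_max), np.log(init.k_m)])
        else:
            z0 = np.array([np.log(init.y_max), np.log(init.k_m), init.tau])
        est._start = lambda X, y, _z0=z0: _z0  # noqa: SLF001 - deliberate hook
    est.fit(curve.times, curve.yields)
    if model_tag == "first_order":
        params: Params = FirstOrderParams(est.y_max_, est.k_m_)
    else:
        params = LogisticParams(est.y_max_, est.k_m_, est.tau_)
    return KineticFit(model_tag=model_tag, params=params, rms=est.rms_,
                      gof=est.gof_, n_iter=est.n_iter_,
                      converged=est.converged_, covariance=est.covariance_)


def gof_ratio(rms: float, y_max: float) -> float:
    """Dimensionless goodness-of-fit indicator ``rms / y_max``.

    ``y_max`` is the fitted asymptotic (limit) yield.  Scale-invariant:
    multiplying both arguments by any c > 0 leaves the ratio unchanged.
    """
    if not y_max > 0:
        raise ValueError(f"y_max must be > 0, got {y_max}")
    if rms < 0:
        raise ValueError(f"rms must be >= 0, got {rms}")
    return rms / y_max
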