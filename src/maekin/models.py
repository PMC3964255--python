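"""Forward kinetic models for solid-liquid extraction yield curves.

Three sigmoidal-family models describe mangiferin yield ``Y(t)`` (mg per g
dry matter) during microwave-assisted extraction:

* a two-parameter pseudo-first-order model
  ``Y(t) = y_max * (1 - exp(-k_m * t))`` — the classic solvent-excess limit
  of second-order solute/solvent kinetics;
* a three-parameter delayed logistic model
  ``Y(t) = y_max / (1 + exp(-k_m * (t - tau)))`` whose time delay ``tau``
  frees the curve from starting at half its asymptote;
* a generalized design-variable model
  ``Y(t, x) = amplitude * (1 - exp(-x / ref)) * logistic(t)`` coupling a
  design variable ``x`` (microwave power in W, or ethanol fraction in % v/v)
  to the shared logistic time course through a saturation scale ``ref``.

All functions here are pure; estimation lives in :mod:`maekin.estimators`
and :mod:`maekin.fitting`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "FirstOrderParams",
    "LogisticParams",
    "GlobalParams",
    "first_order_yield",
    "logistic_yield",
    "global_yield",
    "separable_power_logistic",
]


@dataclass(frozen=True)
class FirstOrderParams:
    """Parameters of the pseudo-first-order extraction model.

    Attributes
    ----------
    y_max : float
        Asymptotic yield as time approaches infinity, mg/g.
    k_m : float
        First-order extraction rate constant, 1/s.
    """

    y_max: float
    k_m: float

    def __post_init__(self) -> None:
        if not self.y_max >= 0:
            raise ValueError(f"y_max must be >= 0, got {self.y_max}")
        if not self.k_m > 0:
            raise ValueError(f"k_m must be > 0, got {self.k_m}")


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the delayed logistic extraction model.

    Attributes
    ----------
    y_max : float
        Asymptotic yield, mg/g.
    k_m : float
        Logistic rate constant, 1/s.
    tau : float
        Time delay shifting the inflection point, s.  May be zero; a
        negative value is tolerated as a degenerate fit and flagged via
        :attr:`degenerate_delay`.
    """

    y_max: float
    k_m: float
    tau: float

    def __post_init__(self) -> None:
        if not self.y_max >= 0:
            raise ValueError(f"y_max must be >= 0, got {self.y_max}")
        if not self.k_m > 0:
            raise ValueError(f"k_m must be > 0, got {self.k_m}")
        if not math.isfinite(self.tau):
            raise ValueError(f"tau must be finite, got {self.tau}")

    @property
    def degenerate_delay(self) -> bool:
        """True when the fitted delay is negative (physically suspect)."""
        return self.tau < 0


@dataclass(frozen=True)
class GlobalParams:
    """Parameters of the design-variable-dependent logistic model.

    Attributes
    ----------
    ref : float
        Saturation scale of the design variable (W for power, % v/v for
        ethanol fraction).
    k_m : float
        Logistic rate constant, 1/s.
    tau : float
        Time delay, s.
    amplitude : float
        Overall yield scale, mg/g.  Profiled out linearly during fitting.
    """

    ref: float
    k_m: float
    tau: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.ref > 0:
            raise ValueError(f"ref must be > 0, got {self.ref}")
        if not self.k_m > 0:
            raise ValueError(f"k_m must be > 0, got {self.k_m}")
        if not math.isfinite(self.tau):
            raise ValueError(f"tau must be finite, got {self.tau}")
        if not self.amplitude >= 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")


def _as_time(t, allow_negative: bool = False):
    t = np.asarray(t, dtype=float)
    if not allow_negative and np.any(t < 0):
        raise ValueError("negative extraction time is outside the model domain")
    return t


def first_order_yield(t, p: FirstOrderParams):
    """Pseudo-first-order yield ``y_max * (1 - exp(-k_m * t))``.

    Parameters
    ----------
    t : array_like
        Extraction time(s), s; must be >= 0.
    p : FirstOrderParams

    Returns
    -------
    ndarray or float
        Yield in mg/g; 0 at ``t = 0``, approaching ``y_max`` as t grows.
    """
    t = _as_time(t)
    out = p.y_max * -np.expm1(-p.k_m * t)
    return out if out.ndim else float(out)


def logistic_yield(t, p: LogisticParams):
    """Delayed logistic yield ``y_max / (1 + exp(-k_m * (t - tau)))``.

    Equals exactly ``y_max / 2`` at ``t = tau``; without the delay the
    curve would always start at half its asymptote.
    """
    t = np.asarray(t, dtype=float)
    from scipy.special import expit

    out = p.y_max * expit(p.k_m * (t - p.tau))
    return out if out.ndim else float(out)


def separable_power_logistic(t, x, ref: float, k_m: float, tau: float):
    """Unit-amplitude separable surface ``(1 - e^{-x/ref}) * logistic(t)``.

    This is the default strategy for the generalized model: a design-variable
    saturation factor times the shared delayed logistic time course.  Any
    callable with this signature can replace it in the global fit.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    from scipy.special import expit

    return -np.expm1(-x / ref) * expit(k_m * (t - tau))


#: Signature shared by all generalized-model strategies.
GlobalStrategy = Callable[..., np.ndarray]


def global_yield(t, x, p: GlobalParams, strategy: GlobalStrategy = separable_power_logistic):
    """Design-variable-dependent yield surface.

    Parameters
    ----------
    t : array_like
        Extraction time(s), s; >= 0.
    x : array_like
        Design-variable value(s) — power in W or ethanol in % v/v; > 0.
    p : GlobalParams
    strategy : callable
        Unit-amplitude surface ``f(t, x, ref, k_m, tau)``; defaults to the
        separable saturation-times-logistic form.

    Returns
    -------
    ndarray or float
        Yield in mg/g, bounded above by ``p.amplitude``.
    """
    t = _as_time(t)
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("design-variable value x must be > 0")
    out = p.amplitude * strategy(t, x, p.ref, p.k_m, p.tau)
    return out if out.ndim else float(out)
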