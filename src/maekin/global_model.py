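"""Joint fitting of a whole one-factor-at-a-time curve family.

An :class:`OFATDataset` holds the balanced grid of yield curves collected
while one design variable (microwave power or ethanol fraction) is varied
and everything else is fixed.  :func:`fit_global` fits the shared
design-variable-dependent logistic surface to the whole family at once,
pooling squared residuals over every retained (level, time) cell and
profiling the linear amplitude out by variable projection.

The 900 W power level is excluded by default: at that power the yield
rises and then degrades, which the monotone model family does not describe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .estimators import GlobalLogisticExtraction
from .fitting import ExtractionCurve, KineticFit
from .models import GlobalParams, separable_power_logistic

__all__ = ["OFATDataset", "fit_global", "DEFAULT_EXCLUSIONS"]

#: Levels dropped from the global fit unless the caller overrides them.
DEFAULT_EXCLUSIONS = {"power": (900.0,), "ethanol": (), "preleach": ()}

_LEVEL_UNITS = {"power": "W", "ethanol": "% v/v", "preleach": "min"}


@dataclass(frozen=True)
class OFATDataset:
    """Balanced one-factor-at-a-time collection of extraction curves.

    Attributes
    ----------
    factor_name : str
        ``power``, ``ethanol`` or ``preleach``.
    levels : ndarray
        Ordered numeric factor levels (W, % v/v or min).
    times : ndarray
        Shared extraction-time grid, s.
    yields : ndarray of shape (n_levels, n_times)
        Yield matrix, mg/g; every level observed at every grid time.
    """

    factor_name: str
    levels: np.ndarray
    times: np.ndarray
    yields: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        times = np.asarray(self.times, dtype=float)
        yields = np.asarray(self.yields, dtype=float)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "yields", yields)
        if yields.shape != (len(levels), len(times)):
            raise ValueError(
                f"yield matrix shape {yields.shape} does not match "
                f"{len(levels)} levels x {len(times)} times")
        if np.any(np.diff(times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if len(np.unique(levels)) != len(levels):
            raise ValueError("levels must be distinct")
        if np.any(yields < 0):
            raise ValueError("yields must be >= 0")

    @property
    def level_unit(self) -> str:
        return _LEVEL_UNITS.get(self.factor_name, "")

    def curve(self, level: float) -> ExtractionCurve:
        """The single :class:`ExtractionCurve` at one factor level."""
        idx = np.flatnonzero(self.levels == level)
        if idx.size != 1:
            raise KeyError(f"level {level} not in dataset")
        return ExtractionCurve(self.factor_name, float(level), self.times,
                               self.yields[idx[0]])

    def curves(self) -> list[ExtractionCurve]:
        return [self.curve(lv) for lv in self.levels]

    def subset(self, exclusions: Iterable[float]) -> "OFATDataset":
        """Dataset with the given levels removed."""
        excl = set(float(e) for e in exclusions)
        keep = np.array([lv not in excl for lv in self.levels])
        if not keep.any():
            raise ValueError("all levels excluded: empty dataset")
        return OFATDataset(self.factor_name, self.levels[keep], self.times,
                           self.yields[keep])

    def long_arrays(self):
        """Flattened ``(t, x, y)`` arrays over every (level, time) cell."""
        tt, xx = np.meshgrid(self.times, self.levels)
        return tt.ravel(), xx.ravel(), self.yields.ravel()


def fit_global(dataset: OFATDataset,
               strategy=separable_power_logistic,
               exclusions: Optional[Sequence[float]] = None,
               fix_ref: Optional[float] = None,
               tol: float = 1e-10, max_iter: int = 500,
               multistart: bool = False, random_state=None) -> KineticFit:
    """Fit the shared design-variable logistic surface to a curve family.

    Parameters
    ----------
    dataset : OFATDataset
    strategy : callable
        Unit-amplitude surface ``f(t, x, ref, k_m, tau)``; the default is
        the separable saturation-times-logistic form.
    exclusions : sequence of float or None
        Factor levels to drop before fitting.  ``None`` applies the factor's
        default (900 W for the power factor); pass ``()`` to keep everything.
    fix_ref : float or None
        Hold the design-variable scale fixed and fit only ``(k_m, tau)``.
    tol, max_iter, multistart, random_state
        Optimizer controls, as in :func:`maekin.fitting.fit_curve`.

    Returns
    -------
    KineticFit
        With :class:`~maekin.models.GlobalParams`; ``gof`` is the pooled
        rms over the maximum fitted yield across the retained cells.
    """
    if exclusions is None:
        exclusions = DEFAULT_EXCLUSIONS.get(dataset.factor_name, ())
    data = dataset.subset(exclusions) if len(tuple(exclusions)) else dataset
    if len(data.levels) < (1 if fix_ref is not None else 2):
        raise ValueError("global fit needs >= 2 retained levels "
                         "(1 when ref is fixed)")
    t, x, y = data.long_arrays()
    est = GlobalLogisticExtraction(strategy=strategy, fix_ref=fix_ref,
                                   tol=tol, max_iter=max_iter,
                                   multistart=multistart,
                                   random_state=random_state)
    est.fit(np.column_stack([t, x]), y)
    params = GlobalParams(ref=est.ref_, k_m=est.k_m_, tau=est.tau_,
                          amplitude=est.amplitude_)
    return KineticFit(model_tag="global", params=params, rms=est.rms_,
                      gof=est.gof_, n_iter=est.n_iter_,
                      converged=est.converged_, covariance=est.covariance_)
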