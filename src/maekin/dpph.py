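"""DPPH radical-scavenging activity and IC50 estimation.

The DPPH assay measures antioxidant capacity by the decolorization of the
stable DPPH radical at 517 nm: the scavenging (inhibition) percentage is
``100 * (A_control - A_sample) / A_control``.  IC50 — the extract
concentration giving 50% inhibition — is estimated by default with
assumption-light linear interpolation of inhibition against
log10(concentration) between the bracketing observations; a four-parameter
logistic (4PL) fit is available behind a flag for smooth dose-response
curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["DoseResponse", "scavenging_percent", "ic50", "four_pl",
           "IC50RangeError"]


class IC50RangeError(ValueError):
    """The inhibition curve never crosses 50% inside the tested range."""


def scavenging_percent(a_control: float, a_sample: float) -> float:
    """Scavenging effect, percent: ``100 * (A_control - A_sample) / A_control``.

    A sample absorbing more than the control gives a negative percentage
    (pro-oxidant artifact); it is returned as-is with a warning.
    """
    if not a_control > 0:
        raise ValueError(f"control absorbance must be > 0, got {a_control}")
    if a_sample < 0:
        raise ValueError(f"sample absorbance must be >= 0, got {a_sample}")
    pct = 100.0 * (a_control - a_sample) / a_control
    if pct < 0:
        warnings.warn("negative scavenging percentage (sample absorbs more "
                      "than the control)", RuntimeWarning)
    return pct


@dataclass(frozen=True)
class DoseResponse:
    """DPPH dose-response table.

    ``inhibition`` is always derived from the absorbances, never supplied:
    the record is constructed from raw 517 nm readings.
    """

    concentrations: np.ndarray
    absorbances: np.ndarray
    control_absorbance: float
    inhibition: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        absb = np.asarray(self.absorbances, dtype=float)
        if conc.ndim != 1 or absb.shape != conc.shape:
            raise ValueError("concentrations and absorbances must be 1-D "
                             "and equally long")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be > 0 (ug/ml)")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not self.control_absorbance > 0:
            raise ValueError("control absorbance must be > 0")
        inhib = np.array([scavenging_percent(self.control_absorbance, a)
                          for a in absb])
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "absorbances", absb)
        object.__setattr__(self, "inhibition", inhib)

    def __len__(self) -> int:
        return len(self.concentrations)


def four_pl(c, bottom, top, ic50_, hill):
    """Four-parameter logistic dose-response curve (log-concentration form)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50_ / c) ** hill)


def _interp_ic50(conc: np.ndarray, inhib: np.ndarray) -> float:
    hits = np.flatnonzero(inhib == 50.0)
    if hits.size:
        return float(conc[hits[0]])
    above = inhib >= 50.0
    if not above.any():
        raise IC50RangeError(
            f"inhibition never reaches 50% (max {inhib.max():.2f}% at "
            f"{conc[np.argmax(inhib)]:g} ug/ml): upper bracket missing")
    j = int(np.argmax(above))  # first index at/above 50
    if j == 0:
        raise IC50RangeError(
            f"inhibition already {inhib[0]:.2f}% at the lowest concentration "
            f"{conc[0]:g} ug/ml: lower bracket missing")
    lo, hi = np.log10(conc[j - 1]), np.log10(conc[j])
    frac = (50.0 - inhib[j - 1]) / (inhib[j] - inhib[j - 1])
    return float(10.0 ** (lo + frac * (hi - lo)))


def ic50(dr: DoseResponse, method: str = "interpolation") -> float:
    """Concentration (ug/ml) giving 50% DPPH inhibition.

    Parameters
    ----------
    dr : DoseResponse
    method : {"interpolation", "4pl"}
        ``interpolation`` (default) linearly interpolates inhibition against
        log10(concentration) between the pair bracketing 50%; ``4pl`` fits a
        four-parameter logistic and reads its midpoint off.

    Raises
    ------
    IC50RangeError
        When 50% is not bracketed inside the tested range, naming the
        missing side.
    """
    conc, inhib = dr.concentrations, dr.inhibition
    if method == "interpolation":
        return _interp_ic50(conc, inhib)
    if method == "4pl":
        _interp_guess = None
        try:
            _interp_guess = _interp_ic50(conc, inhib)
        except IC50RangeError:
            raise
        p0 = [max(float(inhib.min()), 0.0), float(inhib.max()),
              _interp_guess, 1.0]
        bounds = ([-np.inf, -np.inf, conc.min() / 100, 0.05],
                  [np.inf, np.inf, conc.max() * 100, 20.0])
        popt, _ = curve_fit(four_pl, conc, inhib, p0=p0, bounds=bounds,
                            maxfev=20000)
        return float(popt[2])
    raise ValueError(f"unknown IC50 method {method!r}")
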