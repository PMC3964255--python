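"""Synthetic one-factor-at-a-time extraction data.

Emulates the study design behind the analysis: yield-vs-time curves on the
25-point grid {1, 5, 10, ..., 120} s for each level of one design factor —
microwave power {250, 350, 450, 500, 550} W (900 W behind a flag), ethanol
fraction {50, 60, ..., 100} % v/v, or pre-leaching time {1, 5, ..., 30} min
— with additive homoscedastic Gaussian noise (default sd 0.01 mg/g,
truncated below zero) on a sigmoidal truth curve.  The per-level truth
parameters default to the published per-condition fits shipped in
``data/reference_parameters.csv``.

The optional 900 W level is a synthetic stress fixture only: a
rise-then-decay curve (logistic times exponential decay past its onset)
mimicking yield degradation at extreme power; it corresponds to no
published parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fitting import ExtractionCurve
from .global_model import OFATDataset
from .models import (FirstOrderParams, LogisticParams, first_order_yield,
                     logistic_yield)

__all__ = [
    "SimulationConfig",
    "DEFAULT_TIME_GRID",
    "DEFAULT_LEVELS",
    "load_reference_parameters",
    "default_truth",
    "generate_curve",
    "generate_ofat_dataset",
    "generate_replicate_curves",
]

Truth = Union[FirstOrderParams, LogisticParams]

#: Extraction-time grid, s: 1 s then every 5 s up to 120 s (25 points).
DEFAULT_TIME_GRID = np.concatenate(([1.0], np.arange(5.0, 121.0, 5.0)))

#: Factor levels of the screening design (900 W excluded by default).
DEFAULT_LEVELS = {
    "power": (250.0, 350.0, 450.0, 500.0, 550.0),
    "ethanol": (50.0, 60.0, 70.0, 80.0, 90.0, 100.0),
    "preleach": (1.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
}


def load_reference_parameters() -> pd.DataFrame:
    """The shipped per-condition reference fits (both model families)."""
    with resources.files("maekin").joinpath(
            "data/reference_parameters.csv").open() as fh:
        return pd.read_csv(fh)


def default_truth(factor_name: str, model: str = "logistic") -> Dict[float, Truth]:
    """Per-level truth parameters for one factor, from the reference table.

    Parameters
    ----------
    factor_name : {"power", "ethanol", "preleach"}
    model : {"logistic", "first_order"}

    Returns
    -------
    dict mapping level -> parameter container
    """
    if factor_name not in DEFAULT_LEVELS:
        raise ValueError(f"unknown factor {factor_name!r}; expected one of "
                         f"{sorted(DEFAULT_LEVELS)}")
    table = load_reference_parameters()
    sel = table[(table["factor"] == factor_name) & (table["model"] == model)]
    if sel.empty:
        raise ValueError(f"no reference parameters for model {model!r}")
    out: Dict[float, Truth] = {}
    for _, row in sel.iterrows():
        if model == "logistic":
            out[float(row["level"])] = LogisticParams(
                row["y_max"], row["k_m"], row["tau"])
        else:
            out[float(row["level"])] = FirstOrderParams(row["y_max"], row["k_m"])
    return out


def _forward(truth: Truth, t: np.ndarray) -> np.ndarray:
    if isinstance(truth, LogisticParams):
        return np.asarray(logistic_yield(t, truth))
    return np.asarray(first_order_yield(t, truth))


def _rise_decay(t: np.ndarray, base: LogisticParams, decay_rate: float = 0.02,
                peak_time: float = 50.0) -> np.ndarray:
    """Synthetic stress curve: logistic rise, exponential decay past the peak."""
    return np.asarray(logistic_yield(t, base)) * np.exp(
        -decay_rate * np.clip(t - peak_time, 0.0, None))


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one simulated OFAT dataset.

    Attributes
    ----------
    factor_name : which design variable is screened.
    levels : factor levels (units per factor: W, % v/v, min).
    times : shared extraction-time grid, s.
    truths : per-level truth parameters; defaults to the reference fits.
    noise_sd : additive Gaussian noise sd, mg/g (>= 0).
    proportional_noise : when True, the sd scales with the mean yield.
    replicates : independent noisy curves per level (>= 1).
    seed : RNG seed; a single stream drives the whole dataset.
    model : truth family, "logistic" or "first_order".
    include_900 : add the synthetic 900 W rise-then-decay stress level
        (power factor only; no published truth exists for it).
    """

    factor_name: str = "power"
    levels: Optional[Sequence[float]] = None
    times: np.ndarray = field(default_factory=lambda: DEFAULT_TIME_GRID.copy())
    truths: Optional[Dict[float, Truth]] = None
    noise_sd: float = 0.01
    proportional_noise: bool = False
    replicates: int = 1
    seed: int = 0
    model: str = "logistic"
    include_900: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        levels = (tuple(float(v) for v in self.levels)
                  if self.levels is not None
                  else DEFAULT_LEVELS[self.factor_name])
        if self.include_900 and self.factor_name == "power" and 900.0 not in levels:
            levels = levels + (900.0,)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        truths = (dict(self.truths) if self.truths is not None
                  else default_truth(self.factor_name, self.model))
        missing = [lv for lv in levels if lv not in truths and lv != 900.0]
        if missing:
            raise ValueError(f"no truth parameters for levels {missing}")
        object.__setattr__(self, "truths", truths)


def generate_curve(truth: Truth, grid, noise_sd: float = 0.0,
                   seed: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None,
                   proportional: bool = False,
                   factor_name: str = "power", factor_level: float = 0.0,
                   replicate: Optional[int] = None) -> ExtractionCurve:
    """One noisy yield curve: forward model plus i.i.d. Gaussian noise.

    The noise is truncated below zero (yields are concentrations); with the
    default truths the truncation bias is negligible because every yield is
    far above the noise scale.  Reproducible for a fixed ``seed``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("time grid must be nonempty")
    mean = _forward(truth, grid)
    if rng is None:
        rng = np.random.default_rng(seed)
    sd = noise_sd * mean if proportional else noise_sd
    noisy = np.clip(mean + rng.normal(0.0, 1.0, size=grid.shape) * sd, 0.0, None)
    return ExtractionCurve(factor_name, float(factor_level), grid, noisy,
                           replicate=replicate)


def generate_replicate_curves(config: SimulationConfig) -> list[ExtractionCurve]:
    """Every replicate curve of the design, in (level, replicate) order."""
    rng = np.random.default_rng(config.seed)
    curves = []
    for level in config.levels:
        for rep in range(1, config.replicates + 1):
            if level == 900.0 and config.factor_name == "power" \
                    and level not in config.truths:
                base = config.truths[550.0]
                mean = _rise_decay(config.times, base)
                sd = (config.noise_sd * mean if config.proportional_noise
                      else config.noise_sd)
                noisy = np.clip(mean + rng.normal(0.0, 1.0, config.times.shape)
                                * sd, 0.0, None)
                curves.append(ExtractionCurve(config.factor_name, level,
                                              config.times, noisy,
                                              replicate=rep))
                continue
            curves.append(generate_curve(
                config.truths[level], config.times, config.noise_sd, rng=rng,
                proportional=config.proportional_noise,
                factor_name=config.factor_name, factor_level=level,
                replicate=rep))
    return curves


def generate_ofat_dataset(config: SimulationConfig) -> OFATDataset:
    """Balanced simulated dataset: levels x shared time grid.

    Replicates are averaged into the matrix (the ANOVA layout has one
    observation per cell); use :func:`generate_replicate_curves` for the
    individual noisy replicates.
    """
    curves = generate_replicate_curves(config)
    n_lv, n_t = len(config.levels), len(config.times)
    grid = np.zeros((n_lv, n_t))
    for i, level in enumerate(config.levels):
        reps = [c.yields for c in curves if c.factor_level == level]
        grid[i] = np.mean(reps, axis=0)
    return OFATDataset(config.factor_name, np.asarray(config.levels),
                       config.times, grid)
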