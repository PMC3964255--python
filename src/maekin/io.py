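"""Tidy CSV input/output for extraction curves.

The on-disk format is a tidy table with the exact header
``factor,level,time_s,yield_mg_per_g`` plus an optional ``replicate``
column: comma separator, period decimal, UTF-8, no thousands separators.
Times are always seconds; pre-leach factor levels stay in minutes (the
level column never mixes units).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .fitting import ExtractionCurve
from .global_model import OFATDataset

__all__ = ["ParseError", "read_curves", "write_curves", "curves_to_frame"]

REQUIRED_COLUMNS = ("factor", "level", "time_s", "yield_mg_per_g")
OPTIONAL_COLUMNS = ("replicate",)


class ParseError(ValueError):
    """A malformed curve CSV; the message carries the offending line number."""


def _fail(path, line, msg):
    raise ParseError(f"{path}:{line}: {msg}")


def read_curves(path, keep_replicates: bool = False
                ) -> Union[OFATDataset, List[ExtractionCurve]]:
    """Read a tidy curve CSV.

    Replicate rows are averaged per (level, time) unless
    ``keep_replicates`` is set.  When every level shares the full time grid
    (and replicates are averaged) the result is a balanced
    :class:`OFATDataset`; otherwise a list of :class:`ExtractionCurve`.

    Raises
    ------
    ParseError
        Missing column, non-numeric cell or duplicate
        ``(level, time, replicate)`` key — each named with its line number.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            _fail(path, 1, "empty file")
        header = [h.strip() for h in header]
        for col in REQUIRED_COLUMNS:
            if col not in header:
                _fail(path, 1, f"missing required column {col!r} "
                               f"(header must be {','.join(REQUIRED_COLUMNS)}"
                               "[,replicate])")
        for col in header:
            if col not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
                _fail(path, 1, f"unexpected column {col!r}")
        idx = {c: header.index(c) for c in header}
        has_rep = "replicate" in idx

        rows, seen = [], set()
        for ln, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                _fail(path, ln, f"expected {len(header)} fields, got {len(row)}")
            factor = row[idx["factor"]].strip()
            vals = {}
            for col in ("level", "time_s", "yield_mg_per_g"):
                raw = row[idx[col]].strip()
                try:
                    vals[col] = float(raw)
                except ValueError:
                    _fail(path, ln, f"non-numeric {col} value {raw!r}")
            rep = None
            if has_rep:
                raw = row[idx["replicate"]].strip()
                if raw:
                    try:
                        rep = int(raw)
                    except ValueError:
                        _fail(path, ln, f"non-integer replicate {raw!r}")
            key = (factor, vals["level"], vals["time_s"], rep)
            if key in seen:
                _fail(path, ln, f"duplicate (factor, level, time, replicate) "
                                f"row {key}")
            seen.add(key)
            rows.append((factor, vals["level"], vals["time_s"],
                         vals["yield_mg_per_g"], rep))

    if not rows:
        _fail(path, 2, "no data rows")
    df = pd.DataFrame(rows, columns=["factor", "level", "time_s",
                                     "yield", "replicate"])
    if df["factor"].nunique() > 1:
        _fail(path, 2, f"multiple factors in one file: "
                       f"{sorted(df['factor'].unique())}")
    factor = df["factor"].iloc[0]

    if keep_replicates:
        curves = []
        for (level, rep), grp in df.groupby(["level", "replicate"],
                                            dropna=False, sort=True):
            grp = grp.sort_values("time_s")
            curves.append(ExtractionCurve(
                factor, float(level), grp["time_s"].to_numpy(),
                grp["yield"].to_numpy(),
                replicate=None if pd.isna(rep) else int(rep)))
        return curves

    mean = (df.groupby(["level", "time_s"], sort=True)["yield"]
            .mean().reset_index())
    levels = np.sort(mean["level"].unique())
    grids = {lv: mean.loc[mean["level"] == lv, "time_s"].to_numpy()
             for lv in levels}
    ref_grid = grids[levels[0]]
    balanced = all(len(g) == len(ref_grid) and np.array_equal(g, ref_grid)
                   for g in grids.values())
    if balanced and len(levels) > 1:
        mat = np.vstack([
            mean.loc[mean["level"] == lv].sort_values("time_s")["yield"]
            .to_numpy() for lv in levels])
        return OFATDataset(factor, levels, ref_grid, mat)
    return [ExtractionCurve(factor, float(lv),
                            grids[lv],
                            mean.loc[mean["level"] == lv]
                            .sort_values("time_s")["yield"].to_numpy())
            for lv in levels]


def curves_to_frame(data) -> pd.DataFrame:
    """Curves or a dataset as a tidy DataFrame in the on-disk column order."""
    if isinstance(data, OFATDataset):
        data = data.curves()
    recs = []
    for c in data:
        for t, y in zip(c.times, c.yields):
            recs.append({"factor": c.factor_name, "level": c.factor_level,
                         "time_s": t, "yield_mg_per_g": y,
                         "replicate": c.replicate})
    df = pd.DataFrame(recs)
    if df["replicate"].isna().all():
        df = df.drop(columns=["replicate"])
    return df


def write_curves(data, path) -> None:
    """Write curves or a dataset to the tidy CSV format (17 significant
    digits, so a write/read round trip preserves values to 1e-12)."""
    df = curves_to_frame(data)
    df.to_csv(path, index=False, float_format="%.17g")
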