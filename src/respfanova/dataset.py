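"""Tidy container and I/O for crossover time-series data.

A :class:`TrialDataset` holds one value vector per (subject, condition,
variable) triple, all aligned to a single equally spaced time grid in
seconds.  The on-disk representation is a long-format CSV with columns
``subject,condition,variable,time_s,value`` (UTF-8, '.' decimal separator),
one row per observation.

Crossover completeness is enforced on construction: every subject must be
present in both conditions for every variable it contributes to, because
the downstream functional ANOVA contrasts the two conditions at every grid
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import CompletenessError, CoverageError, DomainError, FormatError
from .variables import VariableSpec

CONDITIONS = ("ONB", "FB")

_REQUIRED_COLUMNS = ["subject", "condition", "variable", "time_s", "value"]


@dataclass
class TrialDataset:
    """Per-(subject, condition, variable) series on a common equally spaced grid.

    Parameters
    ----------
    grid : ndarray
        Strictly increasing, equally spaced times in seconds.
    series : mapping
        ``(subject, condition, variable) -> value vector`` aligned to ``grid``.
    transforms_applied : dict
        Per-variable flag recording whether the log transform has been applied.
    """

    grid: np.ndarray
    series: dict[tuple[str, str, str], np.ndarray]
    transforms_applied: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise FormatError("grid must be a 1-D array with at least 2 points")
        steps = np.diff(self.grid)
        if np.any(steps <= 0):
            raise FormatError("grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise FormatError("grid must be equally spaced")
        n = self.grid.size
        for key, vec in self.series.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (n,):
                raise FormatError(
                    f"series {key} has length {vec.shape}, expected ({n},)"
                )
            self.series[key] = vec
        self._check_completeness()
        for v in self.variables:
            self.transforms_applied.setdefault(v, False)

    def _check_completeness(self) -> None:
        by_var: dict[str, dict[str, set[str]]] = {}
        for subj, cond, var in self.series:
            by_var.setdefault(var, {c: set() for c in CONDITIONS})[cond].add(subj)
        for var, conds in by_var.items():
            missing = conds["ONB"] ^ conds["FB"]
            if missing:
                names = ", ".join(sorted(missing))
                raise CompletenessError(
                    f"variable {var!r}: subject(s) {names} present in only one condition"
                )

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _, _ in self.series})

    @property
    def variables(self) -> list[str]:
        return sorted({v for _, _, v in self.series})

    def values_matrix(self, variable: str, condition: str) -> np.ndarray:
        """Stack one condition's series as an (n_subjects, n_grid) matrix.

        Rows follow the sorted subject order of :attr:`subjects`.
        """
        rows = [
            self.series[(s, condition, variable)]
            for s in self.subjects
            if (s, condition, variable) in self.series
        ]
        if not rows:
            raise KeyError(f"no series for variable {variable!r} in {condition}")
        return np.vstack(rows)

    def to_long(self) -> pd.DataFrame:
        """Return the long-format DataFrame representation."""
        records = []
        for (subj, cond, var), vec in sorted(self.series.items()):
            records.append(
                pd.DataFrame(
                    {
                        "subject": subj,
                        "condition": cond,
                        "variable": var,
                        "time_s": self.grid,
                        "value": vec,
                    }
                )
            )
        return pd.concat(records, ignore_index=True)


def write_long_csv(dataset: TrialDataset, path: str | Path) -> None:
    """Write a dataset to the long CSV dialect with full float precision."""
    dataset.to_long().to_csv(path, index=False, float_format="%.17g")


def read_long_csv(path: str | Path) -> TrialDataset:
    """Read and validate a long-format CSV into a :class:`TrialDataset`.

    Raises
    ------
    FormatError
        If a required column is missing or a condition label is unknown.
    CompletenessError
        If a subject appears in only one condition for some variable.
    """
    df = pd.read_csv(path, dtype={"subject": str, "condition": str, "variable": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    bad = sorted(set(df["condition"]) - set(CONDITIONS))
    if bad:
        raise FormatError(f"unknown condition label(s): {', '.join(map(str, bad))}")

    grids = df.groupby(["subject", "condition", "variable"])["time_s"].apply(
        lambda s: tuple(np.sort(s.to_numpy(dtype=float)))
    )
    unique_grids = set(grids)
    if len(unique_grids) != 1:
        raise FormatError("all series must share one common time grid")
    grid = np.array(unique_grids.pop(), dtype=float)

    series: dict[tuple[str, str, str], np.ndarray] = {}
    for (subj, cond, var), sub in df.groupby(["subject", "condition", "variable"]):
        sub = sub.sort_values("time_s")
        series[(str(subj), str(cond), str(var))] = sub["value"].to_numpy(dtype=float)
    return TrialDataset(grid=grid, series=series)


def resample_to_grid(
    times: np.ndarray, values: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Linearly interpolate an arbitrarily sampled series onto a grid.

    No extrapolation is performed: every grid point must lie within the
    observed time range, otherwise :class:`CoverageError` is raised.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if times.size < 2:
        raise CoverageError("need at least 2 raw points to interpolate")
    order = np.argsort(times)
    times, values = times[order], values[order]
    if grid.min() < times[0] or grid.max() > times[-1]:
        raise CoverageError(
            f"grid range [{grid.min()}, {grid.max()}] exceeds observed "
            f"range [{times[0]}, {times[-1]}]"
        )
    return np.interp(grid, times, values)


def apply_transforms(
    dataset: TrialDataset, specs: Mapping[str, VariableSpec] | Iterable[VariableSpec]
) -> TrialDataset:
    """Apply the natural-log transform to flagged variables, exactly once.

    Variables whose spec sets ``log_transform`` are replaced by their natural
    logarithm; ``transforms_applied`` guards against double application, so
    calling this twice is a no-op for already-transformed variables.

    Raises
    ------
    DomainError
        If a flagged variable contains a non-positive value; the message
        names the offending (subject, condition, variable, time) cell.
    """
    if not isinstance(specs, Mapping):
        specs = {s.name: s for s in specs}
    new_series = dict(dataset.series)
    applied = dict(dataset.transforms_applied)
    for var, spec in specs.items():
        if not spec.log_transform or applied.get(var, False):
            continue
        for (subj, cond, v), vec in dataset.series.items():
            if v != var:
                continue
            if np.any(vec <= 0):
                k = int(np.argmax(vec <= 0))
                raise DomainError(
                    f"log transform of {var!r}: non-positive value "
                    f"{vec[k]} at subject={subj}, condition={cond}, "
                    f"time_s={dataset.grid[k]}"
                )
            new_series[(subj, cond, v)] = np.log(vec)
        applied[var] = True
    return TrialDataset(
        grid=dataset.grid.copy(), series=new_series, transforms_applied=applied
    )
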