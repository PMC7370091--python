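"""Typical-error responder classification and proportion tests.

For each variable, the per-subject percentage change between conditions is

    pct_change_j = 100 * (mean_FB(j) - mean_ONB(j)) / mean_ONB(j),

where ``mean_c(j)`` averages subject j's series over the analysis grid on
the untransformed measurement scale.  The typical error (TE) — the
within-subject trial-to-trial variability of a paired design — is the SD of
the difference scores divided by sqrt(2), applied here on the %change
scale.  A subject is a *responder* when their change exceeds 1 TE in the
variable's hypothesized direction (a ``two_sided`` mode, |change| > TE, is
available but not the default).  Whether more than half the sample responds
is assessed with a one-sample proportion test against p0 = 0.5 (exact
binomial tail by default; normal approximation with continuity correction
as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import TrialDataset
from .errors import DegenerateInputError
from .variables import Direction, VariableSpec


@dataclass
class ResponderTable:
    """Responder analysis for one variable (one row of the summary table)."""

    variable: str
    subjects: list[str]
    pct_change: np.ndarray
    te_pct: float
    responder: np.ndarray
    k: int
    n: int
    p_value: float
    fb_mean: float
    fb_sd: float
    onb_mean: float
    onb_sd: float

    @property
    def proportion(self) -> float:
        """Responder proportion in percent, 100*k/n."""
        return 100.0 * self.k / self.n


def percent_change(dataset: TrialDataset, variable: str) -> tuple[list[str], np.ndarray]:
    """Per-subject percentage change of test means, FB relative to ONB.

    Returns the sorted subject list and the aligned %change vector.

    Raises
    ------
    DegenerateInputError
        If some subject's ONB test mean is zero (the message names them).
    """
    subjects = dataset.subjects
    fb = dataset.values_matrix(variable, "FB").mean(axis=1)
    onb = dataset.values_matrix(variable, "ONB").mean(axis=1)
    zero = [s for s, m in zip(subjects, onb) if m == 0.0]
    if zero:
        raise DegenerateInputError(
            f"{variable!r}: zero ONB mean for subject(s) {', '.join(zero)}"
        )
    return subjects, 100.0 * (fb - onb) / onb


def typical_error(pct_changes: np.ndarray) -> float:
    """Typical error on the %change scale: SD of the changes / sqrt(2)."""
    pct_changes = np.asarray(pct_changes, dtype=float)
    if pct_changes.size < 2:
        raise DegenerateInputError("typical error needs at least 2 subjects")
    return float(np.std(pct_changes, ddof=1) / np.sqrt(2.0))


def classify(
    pct_changes: np.ndarray,
    te_pct: float,
    direction: Direction | str,
    *,
    two_sided: bool = False,
) -> np.ndarray:
    """Responder flags: change beyond 1 TE in the hypothesized direction."""
    if te_pct < 0:
        raise ValueError("te_pct must be >= 0")
    pct_changes = np.asarray(pct_changes, dtype=float)
    if two_sided:
        return np.abs(pct_changes) > te_pct
    direction = Direction(direction)
    if direction is Direction.FB_GT_ONB:
        return pct_changes > te_pct
    return pct_changes < -te_pct


def proportion_test(k: int, n: int, p0: float = 0.5, method: str = "exact") -> float:
    """One-sided p-value for "the responder probability exceeds p0".

    ``exact``: binomial tail P(X >= k | n, p0); ``normal_cc``: z-test with
    continuity correction.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if method == "exact":
        return float(stats.binom.sf(k - 1, n, p0))
    if method == "normal_cc":
        if k == 0:
            return 1.0
        z = (k - 0.5 - n * p0) / np.sqrt(n * p0 * (1.0 - p0))
        return float(stats.norm.sf(z))
    raise ValueError(f"unknown method {method!r}")


def analyze_variable(
    dataset: TrialDataset, spec: VariableSpec, *, method: str = "exact"
) -> ResponderTable:
    """Full responder analysis for one variable."""
    subjects, pct = percent_change(dataset, spec.name)
    te = typical_error(pct)
    flags = classify(pct, te, spec.direction)
    k = int(flags.sum())
    n = len(subjects)
    p = proportion_test(k, n, method=method)
    fb_means = dataset.values_matrix(spec.name, "FB").mean(axis=1)
    onb_means = dataset.values_matrix(spec.name, "ONB").mean(axis=1)
    return ResponderTable(
        variable=spec.name,
        subjects=subjects,
        pct_change=pct,
        te_pct=te,
        responder=flags,
        k=k,
        n=n,
        p_value=p,
        fb_mean=float(fb_means.mean()),
        fb_sd=float(fb_means.std(ddof=1)),
        onb_mean=float(onb_means.mean()),
        onb_sd=float(onb_means.std(ddof=1)),
    )


def build_table2(
    dataset: TrialDataset,
    specs: Mapping[str, VariableSpec] | Iterable[VariableSpec],
    *,
    method: str = "exact",
) -> tuple[list[ResponderTable], pd.DataFrame]:
    """Responder summary across variables, ordered by descending responder count.

    Returns the per-variable :class:`ResponderTable` objects and a formatted
    DataFrame (condition means +/- SD, responder count, proportion to one
    decimal, significance star when the exact one-sided p < 0.05).
    """
    if isinstance(specs, Mapping):
        specs = list(specs.values())
    tables = [analyze_variable(dataset, s, method=method) for s in specs]
    tables.sort(key=lambda t: -t.k)
    rows = []
    for t in tables:
        rows.append(
            {
                "variable": t.variable,
                "fb_mean": round(t.fb_mean, 4),
                "fb_sd": round(t.fb_sd, 4),
                "onb_mean": round(t.onb_mean, 4),
                "onb_sd": round(t.onb_sd, 4),
                "responders": t.k,
                "n": t.n,
                "proportion_pct": round(t.proportion, 1),
                "p_value": round(t.p_value, 4),
                "significant": "*" if t.p_value < 0.05 else "",
            }
        )
    return tables, pd.DataFrame(rows)
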