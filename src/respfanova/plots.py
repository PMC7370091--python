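"""Headless-safe figures: posterior bands and responder bar plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .excursion import ExcursionResult
from .fanova import FanovaFit
from .responder import ResponderTable


def band_plot(
    fit: FanovaFit, result: ExcursionResult | None, path: str | Path
) -> None:
    """Posterior mean of the condition effect with a 95% band; excursion
    intervals shaded."""
    t = fit.grid / 60.0
    lo = fit.alpha_mean - 1.96 * fit.alpha_sd
    hi = fit.alpha_mean + 1.96 * fit.alpha_sd
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.fill_between(t, lo, hi, alpha=0.3, label="95% pointwise band")
    ax.plot(t, fit.alpha_mean, lw=1.5, label="posterior mean effect")
    ax.axhline(0.0, color="k", lw=0.8, ls="--")
    if result is not None:
        for a, b in result.intervals:
            ax.axvspan(a, b, color="tab:orange", alpha=0.15)
    ax.set_xlabel("time (min)")
    ax.set_ylabel(f"FB effect on {fit.variable}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def responder_plot(table: ResponderTable, path: str | Path) -> None:
    """Per-participant %change bars with the +/- 1 TE band."""
    order = np.argsort(table.pct_change)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    colors = ["tab:green" if r else "tab:gray" for r in table.responder[order]]
    ax.bar(range(table.n), table.pct_change[order], color=colors)
    ax.axhspan(-table.te_pct, table.te_pct, color="tab:blue", alpha=0.15)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("participant (sorted)")
    ax.set_ylabel(f"% change {table.variable}")
    ax.set_title(
        f"{table.variable}: {table.k}/{table.n} responders (TE = {table.te_pct:.1f}%)",
        fontsize=9,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
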