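"""Trace diagnostics and per-bin posterior summaries.

Effective sample size uses the initial-positive-sequence (Geyer-style)
truncation of the autocorrelation sum, robust on short chains. Highest
posterior density intervals are the shortest contiguous window of
sorted samples. Per-bin summaries report the median, the 95% HPD, and
the fraction of posterior mass below/above zero — net diversification
(lambda - mu) is computed per retained iteration and summarised like
any other quantity. Sign fractions use strict inequalities; exact zeros
are counted separately so the three fractions always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .core import TimeGrid, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .mcmc import Trace

__all__ = ["ess", "apply_burn_in", "hpd", "summarize", "PosteriorSummary", "plot_skyline"]


def ess(series) -> float:
    """Effective sample size ``n / (1 + 2 * sum of autocorrelations)``
    with the sum truncated at the first negative pair of consecutive
    autocorrelations (initial positive sequence)."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValidationError(f"ess needs at least 10 samples, got {n}")
    x = x - x.mean()
    if np.all(x == 0):
        raise ValidationError("ess is undefined for a constant series")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]

    # Geyer: sum pairs rho[2m] + rho[2m+1] while positive
    tau = 0.0
    m = 0
    while 2 * m + 1 < n:
        gamma = rho[2 * m] + rho[2 * m + 1]
        if gamma <= 0:
            break
        tau += gamma
        m += 1
    tau = max(2.0 * tau - 1.0, 1e-12)  # = 1 + 2 * sum_{k>=1} rho_k
    return float(n / tau)


def apply_burn_in(trace, fraction: float):
    """Drop the first ``ceil(fraction * n)`` records of a trace (or any
    DataFrame with one row per retained iteration); at least one record
    always survives."""
    if not 0.0 <= fraction < 1.0:
        raise ValidationError(f"burn-in fraction must be in [0, 1), got {fraction}")
    from .mcmc import Trace  # local import to avoid a cycle

    df = trace.records if isinstance(trace, Trace) else trace
    n_drop = int(np.ceil(fraction * len(df)))
    if len(df) > 0:
        n_drop = min(n_drop, len(df) - 1)
    kept = df.iloc[n_drop:].reset_index(drop=True)
    if isinstance(trace, Trace):
        return Trace(
            records=kept,
            model=trace.model,
            scalar_names=trace.scalar_names,
            acceptance=trace.acceptance,
            ess=trace.ess,
            converged=trace.converged,
        )
    return kept


def hpd(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(prob * n)`` of the
    sorted samples (the highest-posterior-density interval for a
    unimodal posterior)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n == 0:
        raise ValidationError("hpd of an empty sample")
    if not 0.0 < prob < 1.0:
        raise ValidationError(f"prob must be in (0, 1), got {prob}")
    m = int(np.ceil(prob * n))
    if m >= n:
        return (float(x[0]), float(x[-1]))
    if m < 1:
        m = 1
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return (float(x[i]), float(x[i + m - 1]))


@dataclass
class PosteriorSummary:
    """Per-bin, per-quantity posterior table.

    Columns: bin (index, youngest = 0; empty for bin-free quantities),
    quantity, median, hpd_low, hpd_high, frac_negative, frac_positive,
    frac_zero.
    """

    table: pd.DataFrame
    prob: float = 0.95

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PosteriorSummary":
        return cls(table=pd.read_csv(path))

    def row(self, quantity: str, bin_index: int | None = None) -> pd.Series:
        t = self.table
        mask = t["quantity"] == quantity
        if bin_index is not None:
            mask &= t["bin"] == bin_index
        sel = t[mask]
        if len(sel) != 1:
            raise KeyError(f"no unique row for {quantity!r}, bin {bin_index}")
        return sel.iloc[0]


def _summary_row(bin_label, quantity: str, samples: np.ndarray, prob: float) -> dict:
    lo, hi = hpd(samples, prob) if samples.size > 1 else (samples[0], samples[0])
    n = samples.size
    return {
        "bin": bin_label,
        "quantity": quantity,
        "median": float(np.median(samples)),
        "hpd_low": lo,
        "hpd_high": hi,
        "frac_negative": float(np.sum(samples < 0)) / n,
        "frac_positive": float(np.sum(samples > 0)) / n,
        "frac_zero": float(np.sum(samples == 0)) / n,
    }


def summarize(trace, grid: TimeGrid, model: str, prob: float = 0.95) -> PosteriorSummary:
    """Per-bin posterior summary of a (burned-in) trace.

    For the birth-death skyline: lambda, mu, psi and the post-hoc net
    diversification lambda - mu per bin. For the coalescent: the growth
    rate r per bin plus N_f. Medians, HPD bounds and sign fractions per
    quantity.
    """
    df = trace.records if hasattr(trace, "records") else trace
    if len(df) == 0:
        raise ValidationError("cannot summarise an empty trace")
    rows = []
    if model == "bdsky":
        n_bins = grid.n_bins
        for i in range(n_bins):
            lam = df[f"lambda_{i}"].to_numpy()
            mu = df[f"mu_{i}"].to_numpy()
            psi = df[f"psi_{i}"].to_numpy()
            rows.append(_summary_row(i, "lambda", lam, prob))
            rows.append(_summary_row(i, "mu", mu, prob))
            rows.append(_summary_row(i, "psi", psi, prob))
            rows.append(_summary_row(i, "net_diversification", lam - mu, prob))
        if "origin" in df:
            rows.append(_summary_row("", "origin", df["origin"].to_numpy(), prob))
    elif model == "coalescent":
        for i in range(grid.n_bins):
            r = df[f"growth_{i}"].to_numpy()
            rows.append(_summary_row(i, "growth", r, prob))
        rows.append(_summary_row("", "n_final", df["n_final"].to_numpy(), prob))
    else:
        raise ValidationError(f"unknown model {model!r}")
    return PosteriorSummary(table=pd.DataFrame(rows), prob=prob)


def plot_skyline(
    summary: PosteriorSummary,
    grid: TimeGrid,
    quantity: str,
    ax=None,
    color: str = "C0",
):
    """Step-function skyline of per-bin medians with an HPD ribbon; the
    age axis is absolute Ma with the oldest bin on the left. The oldest
    (unbounded) bin is drawn one mean-bin-width wide."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    b = np.asarray(grid.boundaries)
    width = np.diff(b).mean() if len(b) > 1 else 10.0
    edges = np.append(b, b[-1] + width)
    t = summary.table[summary.table["quantity"] == quantity]
    for _, row in t.iterrows():
        i = int(row["bin"])
        x = [edges[i], edges[i + 1]]
        ax.fill_between(x, row["hpd_low"], row["hpd_high"], alpha=0.25, color=color)
        ax.plot(x, [row["median"]] * 2, color=color)
    ax.set_xlabel("Age (Ma)")
    ax.set_ylabel(quantity)
    ax.invert_xaxis()
    return ax
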