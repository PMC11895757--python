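"""Heterochronous Kingman coalescent with a continuous piecewise-
exponential effective species richness N(t).

N(0) = N_f at the reference age and, within grid bin *i*, N changes
exponentially with the bin's diversification rate r_i: positive r_i
means richness grows forward in time, so looking backward N shrinks as
``N(t) = N(edge_i) * exp(-r_i * (t - edge_i))``. The trajectory is
continuous across all bin boundaries and strictly positive.

Looking backward in time, each fossil tip adds a lineage at its age and
each internal node merges two; while k lineages are extant the
coalescent rate is ``k (k-1) / 2 * 1 / N(t)``. Fossil ages are treated
as given — sampling times carry no information about N under this
model.
"""

from __future__ import annotations

import math

import numpy as np

from .core import CoalescentParams, TimeGrid, TimeTree, ValidationError

__all__ = [
    "NTrajectory",
    "effective_size_at",
    "coalescent_intensity",
    "coalescent_log_likelihood",
]


class NTrajectory:
    """Cached piecewise-exponential N(t) and its cumulative coalescent
    intensity ``Lambda(t) = \\int_0^t dt' / N(t')`` (closed form per bin)."""

    def __init__(self, params: CoalescentParams, grid: TimeGrid) -> None:
        params.check_grid(grid)
        self.grid = grid
        self.edges = grid.edges_internal
        self.r = np.asarray(params.growth)
        n = grid.n_bins
        widths = np.diff(self.edges)
        # log N at each bin's young edge: continuity chains the exponentials
        self.logN_edge = np.empty(n)
        self.logN_edge[0] = math.log(params.n_final)
        if n > 1:
            self.logN_edge[1:] = self.logN_edge[0] - np.cumsum(self.r[:-1] * widths)
        # cumulative intensity at each bin's young edge
        self.Lam_edge = np.empty(n)
        self.Lam_edge[0] = 0.0
        for i in range(n - 1):
            self.Lam_edge[i + 1] = self.Lam_edge[i] + self._bin_intensity(i, widths[i])

    def _bin_intensity(self, i, dt):
        """Integral of 1/N over [edge_i, edge_i + dt] (dt may be an array)."""
        r = self.r[i]
        n_edge = math.exp(self.logN_edge[i])
        if r == 0.0:
            return dt / n_edge
        return np.expm1(r * dt) / (r * n_edge)

    def log_n(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValidationError("internal age must be >= 0")
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        idx = np.searchsorted(self.edges, t, side="right") - 1
        out = self.logN_edge[idx] - self.r[idx] * (t - self.edges[idx])
        return float(out[0]) if scalar else out

    def n(self, t):
        return np.exp(self.log_n(t))

    def cumulative_intensity(self, t):
        """Lambda(t), vectorised; additive by construction."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValidationError("internal age must be >= 0")
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        idx = np.searchsorted(self.edges, t, side="right") - 1
        dt = t - self.edges[idx]
        r = self.r[idx]
        n_edge = np.exp(self.logN_edge[idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.Lam_edge[idx] + np.where(
                r == 0.0, dt / n_edge, np.expm1(r * dt) / (r * n_edge)
            )
        return float(out[0]) if scalar else out

    def invert_intensity(self, t0: float, target: float) -> float:
        """Smallest s >= t0 with Lambda(s) - Lambda(t0) = target, or +inf
        when the total remaining intensity is finite and insufficient
        (possible when the oldest bin has negative growth)."""
        lam0 = self.cumulative_intensity(t0)
        goal = lam0 + target
        n = self.grid.n_bins
        i = int(self.grid.bin_of_internal(t0))
        t = t0
        lam_t = lam0
        while True:
            r = self.r[i]
            n_edge = math.exp(self.logN_edge[i])
            rel = t - self.edges[i]
            if i < n - 1:
                lam_next = self.Lam_edge[i + 1]
                if lam_next >= goal:
                    pass  # root lies in this bin
                else:
                    t = self.edges[i + 1]
                    lam_t = lam_next
                    i += 1
                    continue
            need = goal - lam_t
            if r == 0.0:
                return t + need * n_edge
            # solve expm1(r*(s-edge)) - expm1(r*rel) = need * r * n_edge
            arg = math.exp(r * rel) + need * r * n_edge
            if arg <= 0.0:
                return math.inf
            return self.edges[i] + math.log(arg) / r


def effective_size_at(t, params: CoalescentParams, grid: TimeGrid):
    """Effective species richness N at internal age(s) ``t``."""
    return NTrajectory(params, grid).n(t)


def coalescent_intensity(a, b, params: CoalescentParams, grid: TimeGrid):
    """``\\int_a^b dt / N(t)`` for internal ages ``a <= b`` (closed form)."""
    if np.any(np.asarray(a) > np.asarray(b)):
        raise ValidationError("coalescent_intensity requires a <= b")
    traj = NTrajectory(params, grid)
    return traj.cumulative_intensity(b) - traj.cumulative_intensity(a)


def _event_arrays(tree: TimeTree):
    """Ages and kinds (+1 sample-add, -1 coalescence) sorted by age with
    samples first at ties, as seen walking backward from the present."""
    ages = []
    kinds = []
    for nd in tree.preorder():
        nch = len(nd.children)
        if nch == 2:
            ages.append(nd.age)
            kinds.append(-1)
        elif nch == 1:
            raise ValidationError(
                "the coalescent likelihood requires a binary tree without "
                "sampled-ancestor nodes"
            )
        else:
            ages.append(nd.age)
            kinds.append(+1)
    ages = np.asarray(ages)
    kinds = np.asarray(kinds)
    order = np.lexsort((-kinds, ages))  # by age, sample (+1) before coal (-1)
    return ages[order], kinds[order]


def coalescent_log_likelihood(
    tree: TimeTree,
    params: CoalescentParams,
    grid: TimeGrid,
    trajectory: NTrajectory | None = None,
) -> float:
    """Log density of the genealogy under the piecewise-exponential
    coalescent: ``sum over coalescences of -log N(t_c)`` minus
    ``k(k-1)/2`` times the cumulative intensity of every inter-event
    segment. Tip ages are conditioned on, and no origin is scored."""
    if tree.n_tips < 2:
        raise ValidationError("coalescent likelihood needs at least 2 tips")
    params.check_grid(grid)
    traj = trajectory if trajectory is not None else NTrajectory(params, grid)

    ages, kinds = _event_arrays(tree)
    k_after = np.cumsum(kinds)  # lineage count after each event
    if k_after[-1] != 1 or np.any(k_after < 0):
        raise ValidationError("inconsistent event sequence in tree")

    lam = traj.cumulative_intensity(ages)
    seg = np.diff(lam)  # intensity of each inter-event segment
    k_seg = k_after[:-1]  # lineages alive along each segment
    rate = 0.5 * k_seg * (k_seg - 1)

    coal_mask = kinds == -1
    logL = -np.sum(traj.log_n(ages[coal_mask])) - np.sum(rate * seg)
    return float(logL)
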