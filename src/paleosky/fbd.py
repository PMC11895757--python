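"""Fossilised birth-death skyline (BDSKY) log-likelihood.

The model: a birth-death process starts with one species at the origin
(an unknown age older than the root). Within grid bin *i* each lineage
speciates at rate ``lambda_i``, goes extinct at rate ``mu_i`` and
produces a fossil at rate ``psi_i`` (all per lineage per Myr); species
are not removed after sampling, so a fossil may lie on a lineage with
later sampled descendants (a sampled ancestor). Lineages alive at the
reference age (internal t = 0) are sampled there with probability
``rho`` (0 for an entirely extinct clade). The likelihood conditions on
the process producing at least one sample.

Two auxiliary functions drive everything, both running backward in time
(t = age, growing into the past) with continuity across bin boundaries:

``p(t)``
    probability that a lineage alive at age t leaves *no* sampled
    descendants: dp/dt = mu - (lambda+mu+psi) p + lambda p^2, p(0) = 1 - rho.
``q(t)``
    the edge factor: dq/dt = -(lambda+mu+psi) q + 2 lambda p q, q(0) = 1.

Within a bin both have closed forms; the workspace below chains them
across boundaries and evaluates them (and log q, needed because q
underflows at 150+ Myr depths) in O(1) per query after O(n_bins) setup.
"""

from __future__ import annotations

import math

import numpy as np

from .core import BDSKYParams, TimeGrid, TimeTree, ValidationError

__all__ = ["FBDWorkspace", "no_sample_prob", "edge_factor", "fbd_log_likelihood"]

_LOG4 = math.log(4.0)


class FBDWorkspace:
    """Per-parameter-set cache of the piecewise p and q solutions.

    Stores, for every bin, the rates, the discriminant
    ``A = sqrt((lambda-mu-psi)^2 + 4 lambda psi)`` and the boundary
    values of p and log q at the bin's young edge, so that point queries
    reduce to a single closed-form step inside one bin.
    """

    def __init__(self, params: BDSKYParams, grid: TimeGrid) -> None:
        params.check_grid(grid)
        self.grid = grid
        self.edges = grid.edges_internal  # young edge of each bin
        n = grid.n_bins
        self.lam = np.asarray(params.lam)
        self.mu = np.asarray(params.mu)
        self.psi = np.asarray(params.psi)
        self.rho = params.rho
        self.total = self.lam + self.mu + self.psi
        self.A = np.sqrt((self.lam - self.mu - self.psi) ** 2 + 4 * self.lam * self.psi)

        # chain p and log q across bin boundaries, youngest bin first
        self.p_edge = np.empty(n)
        self.logq_edge = np.empty(n)
        self.B = np.empty(n)
        p_prev = 1.0 - params.rho
        logq_prev = 0.0
        for i in range(n):
            self.p_edge[i] = p_prev
            self.logq_edge[i] = logq_prev
            self.B[i] = self._b_coeff(i, p_prev)
            if i < n - 1:
                dt = self.edges[i + 1] - self.edges[i]
                p_prev = self._p_step(i, dt)
                logq_prev = logq_prev + self._logq_step(i, dt)

    def _b_coeff(self, i: int, p0: float) -> float:
        if self.A[i] > 0:
            return ((1.0 - 2.0 * p0) * self.lam[i] + self.mu[i] + self.psi[i]) / self.A[i]
        return 0.0  # unused in the degenerate branches

    def _p_step(self, i, dt):
        """p at age edges[i] + dt, given p at the bin's young edge."""
        lam, mu, psi = self.lam[i], self.mu[i], self.psi[i]
        a, b = self.A[i], self.B[i]
        p0 = self.p_edge[i]
        dt = np.asarray(dt, dtype=float)
        if a > 0 and lam > 0:
            e = np.exp(-a * dt)
            h = ((1 + b) - (1 - b) * e) / ((1 + b) + (1 - b) * e)
            return (lam + mu + psi - a * h) / (2 * lam)
        if lam == 0:
            k = mu + psi
            if k == 0:
                return np.broadcast_to(p0, dt.shape).copy() if dt.ndim else p0
            pinf = mu / k
            return pinf + (p0 - pinf) * np.exp(-k * dt)
        # lam > 0, A == 0: coinciding roots, p* = (lam+mu+psi)/(2 lam)
        pstar = (lam + mu + psi) / (2 * lam)
        u0 = p0 - pstar
        return pstar + u0 / (1.0 - lam * u0 * dt)

    def _logq_step(self, i, dt):
        """log of the within-bin q ratio q(edges[i]+dt)/q(edges[i])."""
        lam, mu, psi = self.lam[i], self.mu[i], self.psi[i]
        a, b = self.A[i], self.B[i]
        dt = np.asarray(dt, dtype=float)
        if a > 0 and lam > 0:
            e = np.exp(-a * dt)
            return _LOG4 - a * dt - 2.0 * np.log((1 + b) + (1 - b) * e)
        if lam == 0:
            return -(mu + psi) * dt
        pstar = (lam + mu + psi) / (2 * lam)
        u0 = self.p_edge[i] - pstar
        return -2.0 * np.log1p(-lam * u0 * dt)

    # -- public queries ------------------------------------------------
    def p(self, t):
        """No-sampled-descendant probability at internal age(s) t."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValidationError("internal age must be >= 0")
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        idx = np.searchsorted(self.edges, t, side="right") - 1
        out = np.empty_like(t)
        for i in np.unique(idx):
            m = idx == i
            out[m] = self._p_step(i, t[m] - self.edges[i])
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar else out

    def log_q(self, t):
        """log q at internal age(s) t (q(0) = 1, continuous across bins)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValidationError("internal age must be >= 0")
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        idx = np.searchsorted(self.edges, t, side="right") - 1
        out = np.empty_like(t)
        for i in np.unique(idx):
            m = idx == i
            out[m] = self.logq_edge[i] + self._logq_step(i, t[m] - self.edges[i])
        return float(out[0]) if scalar else out

    def q(self, t):
        return np.exp(self.log_q(t))

    # -- scalar fast paths (pure math; used by the sampler's O(1) updates)
    def _bin_of(self, t: float) -> int:
        i = int(np.searchsorted(self.edges, t, side="right")) - 1
        return i if i >= 0 else 0

    def p1(self, t: float) -> float:
        i = self._bin_of(t)
        lam, mu, psi = self.lam[i], self.mu[i], self.psi[i]
        a, b = self.A[i], self.B[i]
        p0 = self.p_edge[i]
        dt = t - self.edges[i]
        if a > 0 and lam > 0:
            e = math.exp(-a * dt)
            h = ((1 + b) - (1 - b) * e) / ((1 + b) + (1 - b) * e)
            val = (lam + mu + psi - a * h) / (2 * lam)
        elif lam == 0:
            k = mu + psi
            val = p0 if k == 0 else mu / k + (p0 - mu / k) * math.exp(-k * dt)
        else:
            pstar = (lam + mu + psi) / (2 * lam)
            u0 = p0 - pstar
            val = pstar + u0 / (1.0 - lam * u0 * dt)
        return min(max(val, 0.0), 1.0)

    def log_q1(self, t: float) -> float:
        i = self._bin_of(t)
        lam, mu, psi = self.lam[i], self.mu[i], self.psi[i]
        a, b = self.A[i], self.B[i]
        dt = t - self.edges[i]
        if a > 0 and lam > 0:
            e = math.exp(-a * dt)
            step = _LOG4 - a * dt - 2.0 * math.log((1 + b) + (1 - b) * e)
        elif lam == 0:
            step = -(mu + psi) * dt
        else:
            pstar = (lam + mu + psi) / (2 * lam)
            u0 = self.p_edge[i] - pstar
            step = -2.0 * math.log1p(-lam * u0 * dt)
        return self.logq_edge[i] + step


def no_sample_prob(t, params: BDSKYParams, grid: TimeGrid):
    """Probability that a lineage alive at internal age ``t`` leaves no
    sampled descendants (no fossils, no extant samples at t = 0)."""
    return FBDWorkspace(params, grid).p(t)


def edge_factor(t, params: BDSKYParams, grid: TimeGrid, log: bool = False):
    """The edge factor q(t); with ``log=True`` returns log q(t), which
    stays finite at depths where q itself underflows."""
    ws = FBDWorkspace(params, grid)
    return ws.log_q(t) if log else ws.q(t)


def fbd_log_likelihood(
    tree: TimeTree,
    params: BDSKYParams,
    grid: TimeGrid,
    workspace: FBDWorkspace | None = None,
) -> float:
    """Log probability density of a sampled timetree under the BDSKY model.

    The density decomposes, in log space, as

    * a ``log q(parent) - log q(child)`` ratio per edge, including the
      edge from the origin down to the root;
    * ``log lambda(bin)`` per bifurcation;
    * ``log psi(bin) + log p(age)`` per fossil leaf (sampled, then no
      further sampled descendants);
    * ``log psi(bin)`` per sampled-ancestor fossil (the lineage carries
      on to its sampled descendants, so no p term);
    * ``log rho`` per leaf at age 0 when ``rho > 0``;
    * ``-log(1 - p(origin))`` for conditioning on at least one sample.

    Returns ``-inf`` for observations the parameters make impossible
    (a leaf at age 0 with rho = 0, a zero rate attached to an observed
    event, or no sampling possible at all).
    """
    params.check_grid(grid)
    origin = params.origin_age
    if origin <= tree.root_age:
        raise ValidationError(
            f"origin age {origin} is not older than the root age {tree.root_age}"
        )
    ws = workspace if workspace is not None else FBDWorkspace(params, grid)

    bif_ages = []
    leaf_ages = []
    sa_ages = []
    n_rho = 0
    for nd in tree.preorder():
        nch = len(nd.children)
        if nch == 2:
            bif_ages.append(nd.age)
        elif nch == 1:
            sa_ages.append(nd.age)
        else:
            if nd.age == 0.0:
                if params.rho == 0.0:
                    return -np.inf
                n_rho += 1
            else:
                leaf_ages.append(nd.age)

    logL = 0.0
    with np.errstate(divide="ignore"):
        # conditioning on >= 1 sample
        p_origin = ws.p(origin)
        if p_origin >= 1.0:
            return -np.inf
        logL -= math.log1p(-p_origin)

        logL += ws.log_q(origin)
        if bif_ages:
            x = np.asarray(bif_ages)
            logL += np.sum(ws.log_q(x))
            logL += np.sum(np.log(ws.lam[ws.grid.bin_of_internal(x)]))
        if leaf_ages:
            y = np.asarray(leaf_ages)
            logL -= np.sum(ws.log_q(y))
            logL += np.sum(np.log(ws.psi[ws.grid.bin_of_internal(y)]))
            logL += np.sum(np.log(ws.p(y)))
        if sa_ages:
            z = np.asarray(sa_ages)
            logL += np.sum(np.log(ws.psi[ws.grid.bin_of_internal(z)]))
        if n_rho:
            logL += n_rho * math.log(params.rho)

    if math.isnan(logL):
        return -np.inf
    return float(logL)
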