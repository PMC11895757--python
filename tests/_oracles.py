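"""Independent brute-force oracles used by the tests.

These deliberately avoid the closed forms and data structures of the
package: p and q come from numerical ODE integration, the birth-death
tree density is assembled edge-by-edge from the dense ODE solution, the
constant-size coalescent is a direct transcription of the textbook
formula, and the HPD interval is an exhaustive window search.
"""

from __future__ import annotations

import math
from bisect import bisect_right

import numpy as np
from scipy.integrate import quad, solve_ivp


def ode_pq_solution(params, grid, t_max):
    """Dense solution of the backward ODEs for [p, log q] on [0, t_max]."""
    edges = list(grid.edges_internal)
    lam, mu, psi = params.lam, params.mu, params.psi

    def rhs(s, y):
        i = min(bisect_right(edges, s) - 1, grid.n_bins - 1)
        i = max(i, 0)
        p = y[0]
        tot = lam[i] + mu[i] + psi[i]
        return [mu[i] - tot * p + lam[i] * p * p, -tot + 2 * lam[i] * p]

    return solve_ivp(
        rhs,
        (0.0, t_max * 1.0000001 + 1e-9),
        [1.0 - params.rho, 0.0],
        rtol=1e-11,
        atol=1e-13,
        dense_output=True,
        max_step=1.0,
    ).sol


def fbd_loglik_ode(tree, params, grid):
    """Birth-death-sampling tree density assembled edge-by-edge from the
    numerically integrated p and log q."""
    sol = ode_pq_solution(params, grid, params.origin_age)
    edges = list(grid.edges_internal)

    def bin_of(t):
        return max(min(bisect_right(edges, t) - 1, grid.n_bins - 1), 0)

    def p(t):
        return float(sol(t)[0])

    def logq(t):
        return float(sol(t)[1])

    total = -math.log1p(-p(params.origin_age))
    # edge q-ratios, including the origin edge
    total += logq(params.origin_age) - logq(tree.root.age)
    for nd in tree.preorder():
        for ch in nd.children:
            total += logq(nd.age) - logq(ch.age)
    for nd in tree.preorder():
        b = bin_of(nd.age)
        if len(nd.children) == 2:
            total += math.log(params.lam[b])
        elif len(nd.children) == 1:
            total += math.log(params.psi[b])
        elif nd.age == 0.0:
            total += math.log(params.rho)
        else:
            total += math.log(params.psi[b]) + math.log(p(nd.age))
    return total


def coalescent_loglik_constant(tree, n_e):
    """Heterochronous constant-size coalescent density, straight from
    the textbook definition (no shared code with the implementation)."""
    events = []
    for nd in tree.preorder():
        events.append((nd.age, 0 if nd.is_leaf else 1))
    events.sort()  # sample (0) before coalescence (1) at equal ages
    total = 0.0
    k = 0
    prev = events[0][0]
    for age, kind in events:
        total -= 0.5 * k * (k - 1) * (age - prev) / n_e
        if kind == 0:
            k += 1
        else:
            k -= 1
            total -= math.log(n_e)
        prev = age
    return total


def intensity_quadrature(a, b, params, grid):
    """Adaptive quadrature of 1/N(t) over [a, b]."""
    edges = list(grid.edges_internal)

    def log_n(t):
        i = max(min(bisect_right(edges, t) - 1, grid.n_bins - 1), 0)
        val = math.log(params.n_final)
        for j in range(i):
            val -= params.growth[j] * (edges[j + 1] - edges[j])
        return val - params.growth[i] * (t - edges[i])

    points = [e for e in edges if a < e < b]
    val, _ = quad(lambda t: math.exp(-log_n(t)), a, b, points=points or None, limit=200)
    return val


def hpd_exhaustive(samples, prob=0.95):
    """Minimal window over sorted samples, checked by full enumeration."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    m = int(np.ceil(prob * n))
    m = max(1, min(m, n))
    best = (math.inf, None)
    for i in range(n - m + 1):
        width = x[i + m - 1] - x[i]
        if width < best[0]:
            best = (width, (float(x[i]), float(x[i + m - 1])))
    return best[1]
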