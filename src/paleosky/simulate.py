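"""Forward simulators: fossilised birth-death trees and heterochronous
coalescent genealogies, plus stratigraphic age tables with uncertainty.

These generate synthetic fossil timetrees with the statistical structure
the two likelihoods assume — the stand-in for empirical supertrees. The
birth-death simulator runs the clock forward from the origin with
per-lineage exponential waiting times; rate switches at bin boundaries
are handled by resampling the waiting time from the boundary with the
new rates, valid for exponential clocks by memorylessness. Conditioning
on a minimum number of sampled tips is by rejection, with the retry
count reported so distorted regimes are visible.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass

import numpy as np

from .core import (
    BDSKYParams,
    CoalescentParams,
    Node,
    TimeGrid,
    TimeTree,
    ValidationError,
)
from .coalescent import NTrajectory
from .treeio import AgeRangeTable

__all__ = ["SimResult", "simulate_fbd", "simulate_coalescent", "make_age_table"]


@dataclass
class SimResult:
    """Everything a birth-death simulation produced.

    ``complete_tree`` holds every lineage, sampled or not, with extinct
    lineages ending at their extinction age and survivors at age 0.
    ``sampled_tree`` is the reconstructed fossil tree: terminal fossil
    tips, sampled-ancestor fossils as labelled unary nodes, and origin
    set to the generating origin age. ``fossil_events`` records
    (complete-tree lineage label, fossil age) pairs in simulation order.
    """

    complete_tree: TimeTree
    sampled_tree: TimeTree | None  # None only when min_tips=0 and nothing sampled
    fossil_events: list[tuple[str, float]]
    params: BDSKYParams
    seed: int
    retries: int = 0


def _segment_bin(edges: np.ndarray, age: float) -> int:
    """Bin governing ages just *younger* than ``age`` (an age exactly on
    a boundary is about to enter the next younger bin)."""
    return max(0, int(np.searchsorted(edges, age, side="left")) - 1)


def simulate_fbd(
    params: BDSKYParams,
    grid: TimeGrid,
    seed: int,
    min_tips: int = 2,
    max_lineages: int = 100_000,
    max_retries: int = 1000,
) -> SimResult:
    """Exact stochastic simulation of the piecewise birth-death-sampling
    process from a single lineage at the origin.

    Retries (rejection) until the reconstructed fossil tree has at least
    ``min_tips`` terminal tips, mirroring the likelihood's conditioning
    on sampling. With ``rho > 0`` each lineage alive at age 0 is
    additionally sampled there with that probability.

    Raises
    ------
    RuntimeError
        If a single replicate exceeds ``max_lineages`` (the parameters
        imply an unmanageably large tree — shorten the duration or lower
        the net diversification), or if ``max_retries`` replicates all
        fail the conditioning (e.g. psi = 0 everywhere with rho = 0).
    """
    params.check_grid(grid)
    edges = grid.edges_internal
    lam = np.asarray(params.lam)
    mu = np.asarray(params.mu)
    psi = np.asarray(params.psi)
    total = lam + mu + psi
    rng = np.random.default_rng(seed)

    for attempt in range(max_retries):
        counter = {"lineages": 0, "fossil": 0}
        fossils: dict[int, list[float]] = {}  # id(node) -> ages on edge above
        rho_sampled: set[int] = set()  # id(node) of survivors sampled at t=0
        events: list[tuple[str, float]] = []

        def new_label(prefix: str) -> str:
            counter["lineages"] += 1
            return f"{prefix}{counter['lineages']}"

        def sim_lineage(start_age: float) -> Node:
            """Simulate one lineage from ``start_age`` toward the present;
            returns the complete-tree node ending the lineage."""
            if counter["lineages"] >= max_lineages:
                raise RuntimeError(
                    f"simulation exceeded {max_lineages} lineages; the "
                    "parameters imply an unmanageably large tree (reduce the "
                    "origin age or the net diversification rate)"
                )
            edge_fossils: list[float] = []
            a = start_age
            while True:
                i = _segment_bin(edges, a)
                floor = edges[i] if i > 0 else 0.0
                rate = total[i]
                cand = a - rng.exponential(1.0 / rate) if rate > 0 else floor
                if cand <= floor:
                    if i > 0:
                        a = floor  # re-draw with the next bin's rates
                        continue
                    # reached the reference age alive
                    node = Node(age=0.0, label=new_label("S"))
                    if params.rho > 0 and rng.random() < params.rho:
                        rho_sampled.add(id(node))
                    break
                u = rng.random() * rate
                if u < lam[i]:  # speciation
                    node = Node(age=cand, label=new_label("N"))
                    node.add_child(sim_lineage(cand))
                    node.add_child(sim_lineage(cand))
                    break
                elif u < lam[i] + mu[i]:  # extinction
                    node = Node(age=cand, label=new_label("X"))
                    break
                else:  # fossil sample; lineage continues
                    edge_fossils.append(cand)
                    counter["fossil"] += 1
                    a = cand
            if edge_fossils:
                fossils[id(node)] = edge_fossils
            for age in edge_fossils:
                events.append((node.label, age))
            return node

        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old_limit, 20_000))
        try:
            complete_root = sim_lineage(params.origin_age)
        finally:
            sys.setrecursionlimit(old_limit)

        sampled_tree = _reconstruct_sampled(
            complete_root, fossils, rho_sampled, params.origin_age
        )
        accepted = (
            min_tips == 0
            if sampled_tree is None
            else sampled_tree.n_tips >= min_tips
        )
        if accepted:
            complete = TimeTree(
                complete_root,
                origin_age=params.origin_age,
                reference_age=grid.reference_age,
            )
            if sampled_tree is not None:
                sampled_tree.reference_age = grid.reference_age
            return SimResult(
                complete_tree=complete,
                sampled_tree=sampled_tree,
                fossil_events=events,
                params=params,
                seed=seed,
                retries=attempt,
            )

    raise RuntimeError(
        f"no replicate with >= {min_tips} sampled tips in {max_retries} "
        "attempts; with these rates the sampling conditioning (>= 1 fossil) "
        "may be impossible (e.g. psi = 0 everywhere with rho = 0)"
    )


def _reconstruct_sampled(
    complete_root: Node,
    fossils: dict[int, list[float]],
    rho_sampled: set[int],
    origin_age: float,
) -> TimeTree | None:
    """Prune the complete tree to its fossil (and rho-) samples.

    Fossils on an edge wrap the subtree below it: the youngest becomes a
    terminal tip if nothing below was sampled, otherwise a labelled
    unary sampled-ancestor node. Speciation events with a single sampled
    descendant side are suppressed.
    """
    counter = {"f": 0, "s": 0}

    def rec(nd: Node) -> Node | None:
        subs = [s for s in (rec(ch) for ch in nd.children) if s is not None]
        if len(subs) == 2:
            sub = Node(age=nd.age, children=subs)
        elif len(subs) == 1:
            sub = subs[0]
        else:
            sub = None
            if nd.is_leaf and id(nd) in rho_sampled:
                counter["s"] += 1
                sub = Node(age=0.0, label=f"S{counter['s']}")
        for age in sorted(fossils.get(id(nd), [])):  # youngest first
            counter["f"] += 1
            label = f"F{counter['f']}"
            if sub is None:
                sub = Node(age=age, label=label)
            else:
                sub = Node(age=age, label=label, children=[sub])
        return sub

    root = rec(complete_root)
    if root is None:
        return None
    return TimeTree(root, origin_age=origin_age)


def simulate_coalescent(
    tip_ages,
    params: CoalescentParams,
    grid: TimeGrid,
    seed: int,
    labels: list[str] | None = None,
) -> TimeTree:
    """Heterochronous coalescent simulation under the piecewise-
    exponential trajectory, by time-rescaling: while k lineages are
    extant, the next coalescence solves ``k(k-1)/2 * (Lambda(s) -
    Lambda(t)) = E`` with ``E ~ Exp(1)``, interrupted whenever an older
    tip joins. Reproducible given the seed.
    """
    tip_ages = [float(a) for a in tip_ages]
    if len(tip_ages) < 2:
        raise ValidationError("need at least 2 tips to simulate a genealogy")
    if any(a < 0 for a in tip_ages):
        raise ValidationError("tip ages must be >= 0 (internal coordinate)")
    params.check_grid(grid)
    if labels is None:
        labels = [f"T{i + 1}" for i in range(len(tip_ages))]
    if len(labels) != len(tip_ages):
        raise ValidationError("labels and tip_ages lengths differ")

    traj = NTrajectory(params, grid)
    rng = np.random.default_rng(seed)

    order = np.argsort(tip_ages, kind="stable")
    pending = [(tip_ages[i], labels[i]) for i in order]
    active: list[Node] = []
    t = pending[0][0]
    ptr = 0
    while len(active) > 1 or ptr < len(pending):
        next_tip = pending[ptr][0] if ptr < len(pending) else math.inf
        k = len(active)
        s = math.inf
        if k >= 2:
            e = rng.exponential(1.0)
            s = traj.invert_intensity(t, e / (0.5 * k * (k - 1)))
        if s <= next_tip and math.isfinite(s):
            i, j = rng.choice(k, size=2, replace=False)
            a, b = active[i], active[j]
            parent = Node(age=s, children=[a, b])
            active = [nd for m, nd in enumerate(active) if m not in (i, j)]
            active.append(parent)
            t = s
        else:
            if math.isinf(next_tip):
                raise RuntimeError(
                    "lineages failed to coalesce: the cumulative coalescent "
                    "intensity in the unbounded oldest bin is finite "
                    "(negative growth backward in time makes non-coalescence "
                    "possible); adjust the oldest bin's growth rate"
                )
            age, lab = pending[ptr]
            active.append(Node(age=age, label=lab))
            ptr += 1
            t = age
    return TimeTree(active[0], reference_age=grid.reference_age)


def make_age_table(
    sim: SimResult | TimeTree,
    halfwidth: float,
    seed: int | None = None,
) -> AgeRangeTable:
    """Stratigraphic bounds for every fossil sample of a simulated tree:
    true age plus/minus ``halfwidth`` Myr, truncated at the reference
    age, so the implied uniform tip prior always covers the truth.

    With a ``seed`` the window of width ``2 * halfwidth`` is instead
    placed uniformly at random around each true age, making the true age
    uniform within its reported bounds rather than always central.
    """
    if halfwidth < 0:
        raise ValidationError("halfwidth must be >= 0")
    tree = sim.sampled_tree if isinstance(sim, SimResult) else sim
    ref = tree.reference_age
    rng = None if seed is None else np.random.default_rng(seed)
    ranges: dict[str, tuple[float, float]] = {}
    for nd in tree.sample_nodes():
        true_abs = nd.age + ref
        shift = 0.0 if rng is None else rng.uniform(-halfwidth, halfwidth)
        oldest = true_abs + halfwidth + shift
        youngest = max(ref, oldest - 2.0 * halfwidth)
        ranges[nd.label] = (oldest, youngest)
    return AgeRangeTable(ranges)
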