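"""Metropolis–Hastings proposal kernels.

Each kernel returns ``(proposal, log_hastings_ratio)`` or ``None`` when
the move is degenerate (empty support), in which case the sampler
counts a rejection. Age moves draw uniformly within the hard interval
allowed by the tree and any stratigraphic bounds; because that interval
does not depend on the current value, the proposal is symmetric and the
Hastings ratio is zero.
"""

from __future__ import annotations

import math

import numpy as np

from .core import Node, TimeTree, ValidationError

__all__ = ["scale_move", "window_move", "node_age_interval", "sample_age_interval"]


def scale_move(
    value: float, step: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Multiplicative proposal for positive parameters: ``value * s``
    with ``s = exp(step * u)``, ``u ~ U(-1, 1)``; the Hastings ratio of
    this symmetric-in-log kernel is ``log s``."""
    if value <= 0:
        raise ValidationError(f"scale_move requires a positive value, got {value}")
    s = math.exp(step * (2.0 * rng.random() - 1.0))
    return value * s, math.log(s)


def window_move(
    value: float, step: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Symmetric sliding-window proposal: ``value + step * u``,
    ``u ~ U(-1, 1)``; Hastings ratio 0."""
    return value + step * (2.0 * rng.random() - 1.0), 0.0


def node_age_interval(
    node: Node, origin_age: float | None
) -> tuple[float, float] | None:
    """Allowed age interval for an internal (bifurcation) node: between
    its oldest child and its parent (the origin, for the root). Returns
    None when the root has no parent and no origin — the caller should
    then use a reflected window instead."""
    lo = max(ch.age for ch in node.children)
    if node.parent is not None:
        return (lo, node.parent.age)
    if origin_age is not None:
        return (lo, origin_age)
    return None


def sample_age_interval(
    tree: TimeTree, node: Node
) -> tuple[float, float] | None:
    """Allowed age interval for a fossil sample (leaf or sampled
    ancestor): the intersection of its stratigraphic bounds with the
    ages its neighbours permit. None when empty or when the sample has
    no (or degenerate) bounds."""
    bounds = tree.tip_bounds.get(node.label)
    if bounds is None:
        return None
    oldest, youngest = bounds
    if oldest == youngest:
        return None
    lo = youngest
    hi = oldest
    if node.children:  # sampled ancestor: stay older than its child
        lo = max(lo, node.children[0].age)
    if node.parent is not None:
        hi = min(hi, node.parent.age)
    elif tree.origin_age is not None:
        hi = min(hi, tree.origin_age)
    if hi <= lo:
        return None
    return (lo, hi)
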