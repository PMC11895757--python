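"""Domain types shared by every model: the geological time grid, the
time-calibrated tree, and the parameter containers.

Coordinate conventions
----------------------
Absolute ages are Ma before present. The *internal* coordinate used by all
likelihood code measures Myr backwards from the youngest grid boundary
(``TimeGrid.reference_age``), so t = 0 at the analysis "present" (for the
end-Cretaceous grid, the K-Pg boundary at 66.0 Ma) and t grows into the
past. Bins are half-open ``[young, old)`` in age: a bin contains every
age from its young edge (inclusive) up to its old edge (exclusive), so an
event exactly on a change time belongs to the interval whose floor that
change time is (e.g. 89.8 Ma falls in the 89.8–121.4 Ma bin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "TimeGrid",
    "make_time_grid",
    "bin_index",
    "to_internal_age",
    "from_internal_age",
    "Node",
    "TimeTree",
    "BDSKYParams",
    "CoalescentParams",
    "MESOZOIC_GRID_BOUNDARIES",
]

#: Change times (absolute Ma) of the eight geological bins used for the
#: dinosaur analyses: Coniacian–Maastrichtian (66.0–89.8), Aptian–Turonian
#: (89.8–121.4), Berriasian–Barremian (121.4–145.0), Late Jurassic
#: (145.0–161.5), Middle Jurassic (161.5–174.7), Early Jurassic
#: (174.7–201.4), Late Triassic (201.4–237.0) and Early–Mid Triassic
#: (prior to 237.0).
MESOZOIC_GRID_BOUNDARIES = (66.0, 89.8, 121.4, 145.0, 161.5, 174.7, 201.4, 237.0)


class ValidationError(ValueError):
    """Raised when an input violates a documented model invariant."""


@dataclass(frozen=True)
class TimeGrid:
    """Ordered bin boundaries defining the piecewise intervals.

    Attributes
    ----------
    boundaries:
        Strictly increasing absolute ages in Ma. ``boundaries[0]`` is the
        reference age (the analysis "present"); the oldest bin is
        unbounded above.
    """

    boundaries: tuple[float, ...]

    @property
    def reference_age(self) -> float:
        return self.boundaries[0]

    @property
    def n_bins(self) -> int:
        return len(self.boundaries)

    @property
    def edges_internal(self) -> np.ndarray:
        """Bin lower (young) edges in internal coordinates; edge 0 is 0.0."""
        b = np.asarray(self.boundaries)
        return b - b[0]

    def bin_of_internal(self, t: float | np.ndarray) -> int | np.ndarray:
        """Bin index of an internal age (vectorised).

        Bin *i* covers internal ages ``[edge_i, edge_{i+1})``; ages at or
        beyond the oldest edge map to the oldest bin.
        """
        t_arr = np.asarray(t)
        if np.any(t_arr < 0):
            raise ValidationError(
                "internal age < 0 (younger than the grid reference age)"
            )
        idx = np.searchsorted(self.edges_internal, t_arr, side="right") - 1
        if np.ndim(t) == 0:
            return int(idx)
        return idx


def make_time_grid(boundaries_ma: Sequence[float]) -> TimeGrid:
    """Build a :class:`TimeGrid` from absolute Ma boundaries (any order).

    Raises
    ------
    ValidationError
        If a boundary is non-finite, non-positive, or duplicated.
    """
    if len(boundaries_ma) < 1:
        raise ValidationError("a time grid needs at least one boundary")
    vals = []
    for b in boundaries_ma:
        b = float(b)
        if not math.isfinite(b):
            raise ValidationError(f"non-finite grid boundary: {b!r}")
        if b <= 0:
            raise ValidationError(f"grid boundary must be positive, got {b!r}")
        vals.append(b)
    vals.sort()
    for a, b in zip(vals, vals[1:]):
        if a == b:
            raise ValidationError(f"duplicate grid boundary: {a!r}")
    return TimeGrid(boundaries=tuple(vals))


def bin_index(age_ma: float, grid: TimeGrid) -> int:
    """Bin index of an absolute age in Ma.

    Raises :class:`ValidationError` for ages younger than the reference.
    """
    if age_ma < grid.reference_age:
        raise ValidationError(
            f"age {age_ma} Ma is younger than the grid reference "
            f"({grid.reference_age} Ma)"
        )
    return int(grid.bin_of_internal(age_ma - grid.reference_age))


def to_internal_age(absolute_ma: float, grid: TimeGrid) -> float:
    """Absolute Ma -> Myr before the grid reference age."""
    if absolute_ma < grid.reference_age:
        raise ValidationError(
            f"age {absolute_ma} Ma is younger than the grid reference "
            f"({grid.reference_age} Ma)"
        )
    return absolute_ma - grid.reference_age


def from_internal_age(internal: float, grid: TimeGrid) -> float:
    """Myr before the grid reference age -> absolute Ma."""
    if internal < 0:
        raise ValidationError(f"internal age must be >= 0, got {internal}")
    return internal + grid.reference_age


class Node:
    """A node of a :class:`TimeTree`.

    ``age`` is in the tree's internal coordinate. Leaves carry a label and
    represent fossil samples (or present-day samples at age 0). Internal
    nodes with two children are bifurcations; an internal node with exactly
    one child and a label is a *sampled ancestor* — a fossil sample on a
    lineage that also left sampled descendants.
    """

    __slots__ = ("age", "label", "children", "parent")

    def __init__(
        self,
        age: float = 0.0,
        label: Optional[str] = None,
        children: Optional[list["Node"]] = None,
    ) -> None:
        self.age = float(age)
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        for ch in children or []:
            self.add_child(ch)

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_sampled_ancestor(self) -> bool:
        return len(self.children) == 1 and self.label is not None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"{len(self.children)}-child"
        return f"<Node {self.label or ''} age={self.age:.4g} {kind}>"


class TimeTree:
    """Rooted time-calibrated tree with per-sample stratigraphic bounds.

    Node ages are stored in the internal coordinate (Myr before
    ``reference_age``); ``reference_age`` records the absolute Ma of the
    internal zero so I/O can convert back. ``tip_bounds`` maps a sample
    label to its permissible ``(oldest, youngest)`` age pair, also in
    internal coordinates; a missing entry means the age is fixed.
    ``origin_age`` is the optional start of the birth-death process, older
    than the root.
    """

    def __init__(
        self,
        root: Node,
        origin_age: Optional[float] = None,
        reference_age: float = 0.0,
        tip_bounds: Optional[dict[str, tuple[float, float]]] = None,
    ) -> None:
        self.root = root
        self.origin_age = None if origin_age is None else float(origin_age)
        self.reference_age = float(reference_age)
        self.tip_bounds: dict[str, tuple[float, float]] = dict(tip_bounds or {})
        self.validate()

    # -- traversal -----------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def leaves(self) -> list[Node]:
        return [nd for nd in self.preorder() if nd.is_leaf]

    def sample_nodes(self) -> list[Node]:
        """Leaves plus sampled-ancestor nodes, i.e. every fossil sample."""
        return [
            nd for nd in self.preorder() if nd.is_leaf or nd.is_sampled_ancestor
        ]

    def bifurcations(self) -> list[Node]:
        return [nd for nd in self.preorder() if len(nd.children) == 2]

    @property
    def tip_labels(self) -> list[str]:
        return [nd.label for nd in self.leaves()]

    @property
    def sample_labels(self) -> list[str]:
        return [nd.label for nd in self.sample_nodes()]

    @property
    def n_tips(self) -> int:
        return len(self.leaves())

    @property
    def root_age(self) -> float:
        return self.root.age

    def find(self, label: str) -> Node:
        for nd in self.preorder():
            if nd.label == label:
                return nd
        raise KeyError(label)

    # -- validation / copying -----------------------------------------
    def validate(self) -> None:
        seen: set[str] = set()
        for nd in self.preorder():
            if len(nd.children) > 2:
                raise ValidationError(
                    f"polytomy at node {nd.label or '<unnamed>'}: "
                    f"{len(nd.children)} children (trees must be bifurcating)"
                )
            if len(nd.children) == 1 and nd.label is None:
                raise ValidationError(
                    "unlabelled unary node: only sampled-ancestor fossils "
                    "may have a single child"
                )
            if nd.age < 0:
                raise ValidationError(
                    f"node {nd.label or '<unnamed>'} has negative internal "
                    f"age {nd.age}"
                )
            for ch in nd.children:
                if ch.age > nd.age:
                    raise ValidationError(
                        f"child {ch.label or '<unnamed>'} "
                        f"(age {ch.age}) is older than its parent (age {nd.age})"
                    )
            if nd.label is not None and (nd.is_leaf or nd.is_sampled_ancestor):
                if nd.label in seen:
                    raise ValidationError(f"duplicate sample label {nd.label!r}")
                seen.add(nd.label)
        if self.origin_age is not None and self.origin_age <= self.root.age:
            raise ValidationError(
                f"origin age {self.origin_age} must be older than the root "
                f"age {self.root.age}"
            )
        for label, (oldest, youngest) in self.tip_bounds.items():
            if oldest < youngest:
                raise ValidationError(
                    f"bounds for {label!r} have oldest < youngest"
                )
        for nd in self.sample_nodes():
            bounds = self.tip_bounds.get(nd.label)
            if bounds is not None:
                oldest, youngest = bounds
                if not (youngest <= nd.age <= oldest):
                    raise ValidationError(
                        f"sample {nd.label!r} age {nd.age} outside bounds "
                        f"({oldest}, {youngest})"
                    )

    def copy(self) -> "TimeTree":
        def clone(nd: Node) -> Node:
            new = Node(age=nd.age, label=nd.label)
            for ch in nd.children:
                new.add_child(clone(ch))
            return new

        return TimeTree(
            clone(self.root),
            origin_age=self.origin_age,
            reference_age=self.reference_age,
            tip_bounds=dict(self.tip_bounds),
        )

    def is_binary(self) -> bool:
        """True when the tree has no sampled-ancestor (unary) nodes."""
        return all(len(nd.children) != 1 for nd in self.preorder())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<TimeTree {self.n_tips} tips, root age {self.root_age:.4g}, "
            f"origin {self.origin_age}>"
        )


def _check_rates(name: str, rates: tuple[float, ...], n_bins: int) -> None:
    if len(rates) != n_bins:
        raise ValidationError(
            f"{name} has length {len(rates)}, expected n_bins={n_bins}"
        )
    for v in rates:
        if not math.isfinite(v):
            raise ValidationError(f"{name} contains non-finite value {v!r}")


@dataclass(frozen=True)
class BDSKYParams:
    """Fossilised birth-death skyline parameters.

    Rates are per lineage per Myr, one entry per grid bin, youngest bin
    first. ``rho`` is the extant-sampling probability at the reference age
    (0 for an entirely extinct clade). ``origin_age`` is in the internal
    coordinate.
    """

    origin_age: float
    lam: tuple[float, ...]
    mu: tuple[float, ...]
    psi: tuple[float, ...]
    rho: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lam", tuple(float(v) for v in self.lam))
        object.__setattr__(self, "mu", tuple(float(v) for v in self.mu))
        object.__setattr__(self, "psi", tuple(float(v) for v in self.psi))
        for name in ("lam", "mu", "psi"):
            if any(v < 0 for v in getattr(self, name)):
                raise ValidationError(f"{name} rates must be >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError(f"rho must lie in [0, 1], got {self.rho}")
        if self.origin_age <= 0:
            raise ValidationError("origin_age must be positive (internal age)")

    def check_grid(self, grid: TimeGrid) -> None:
        _check_rates("lambda", self.lam, grid.n_bins)
        _check_rates("mu", self.mu, grid.n_bins)
        _check_rates("psi", self.psi, grid.n_bins)


@dataclass(frozen=True)
class CoalescentParams:
    """Piecewise-exponential coalescent parameters.

    ``growth[i]`` is the diversification rate r_i (per Myr) in bin i,
    positive meaning richness increases forward in time, so the effective
    size shrinks as age increases within the bin. ``n_final`` is the
    effective species richness N_f at the reference age.
    """

    growth: tuple[float, ...]
    n_final: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "growth", tuple(float(v) for v in self.growth))
        if not math.isfinite(self.n_final) or self.n_final <= 0:
            raise ValidationError(f"n_final must be > 0, got {self.n_final}")
        for v in self.growth:
            if not math.isfinite(v):
                raise ValidationError(f"growth contains non-finite value {v!r}")

    def check_grid(self, grid: TimeGrid) -> None:
        _check_rates("growth", self.growth, grid.n_bins)
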