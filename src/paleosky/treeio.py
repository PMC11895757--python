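"""Tree and age-range-table I/O, taxon subsetting, and stratigraphic
tip constraints.

Trees are exchanged as Newick or NEXUS (via dendropy) with branch
lengths in Myr. A tree file alone fixes only relative ages; absolute
calibration comes from an explicit anchor age for the youngest tip or
from an age-range table. Fossil age ranges arrive as CSV with columns
``taxon,oldest_ma,youngest_ma`` — the shape of Paleobiology Database
species first/last-appearance exports. Taxon matching is exact string
equality after underscore/space normalisation; no fuzzy matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd

from .core import Node, TimeTree, ValidationError

__all__ = [
    "AgeRangeTable",
    "read_tree",
    "write_tree",
    "read_age_table",
    "write_age_table",
    "prune_taxa",
    "extract_clade",
    "attach_tip_constraints",
]


def _norm(name: str) -> str:
    return name.strip().replace(" ", "_")


@dataclass(frozen=True)
class AgeRangeTable:
    """Stratigraphic age ranges: taxon -> (oldest, youngest) in absolute Ma."""

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for taxon, (oldest, youngest) in self.ranges.items():
            if not (math.isfinite(oldest) and math.isfinite(youngest)):
                raise ValidationError(f"non-finite age for taxon {taxon!r}")
            if youngest < 0:
                raise ValidationError(f"negative age for taxon {taxon!r}")
            if oldest < youngest:
                raise ValidationError(
                    f"taxon {taxon!r} has oldest ({oldest}) < youngest "
                    f"({youngest})"
                )

    def __len__(self) -> int:
        return len(self.ranges)

    def __contains__(self, taxon: str) -> bool:
        return _norm(taxon) in self.ranges

    def __getitem__(self, taxon: str) -> tuple[float, float]:
        return self.ranges[_norm(taxon)]


def read_age_table(path: str | Path) -> AgeRangeTable:
    """Read a ``taxon,oldest_ma,youngest_ma`` CSV into an AgeRangeTable."""
    df = pd.read_csv(path)
    required = {"taxon", "oldest_ma", "youngest_ma"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"age table {path} is missing column(s): {sorted(missing)}"
        )
    for col in ("oldest_ma", "youngest_ma"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValidationError(f"age table column {col!r} is not numeric")
        if df[col].isna().any():
            raise ValidationError(f"age table column {col!r} has missing values")
    ranges: dict[str, tuple[float, float]] = {}
    for row in df.itertuples(index=False):
        taxon = _norm(str(row.taxon))
        if taxon in ranges:
            raise ValidationError(f"duplicate taxon in age table: {taxon!r}")
        ranges[taxon] = (float(row.oldest_ma), float(row.youngest_ma))
    return AgeRangeTable(ranges)


def write_age_table(table: AgeRangeTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [(t, o, y) for t, (o, y) in table.ranges.items()],
        columns=["taxon", "oldest_ma", "youngest_ma"],
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# tree reading / writing
# ---------------------------------------------------------------------------

def _to_dendropy(tree: TimeTree) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def build(nd: Node, dnd: dendropy.Node) -> None:
        for ch in nd.children:
            dch = dendropy.Node()
            dch.edge.length = nd.age - ch.age
            if ch.is_leaf:
                dch.taxon = taxa.require_taxon(label=ch.label)
            elif ch.label is not None:
                dch.label = ch.label
            dnd.add_child(dch)
            build(ch, dch)

    root = tree.root
    if root.is_leaf:
        dtree.seed_node.taxon = taxa.require_taxon(label=root.label)
    elif root.label is not None:
        dtree.seed_node.label = root.label
    build(root, dtree.seed_node)
    if tree.origin_age is not None:
        dtree.seed_node.edge.length = tree.origin_age - root.age
    return dtree


def write_tree(tree: TimeTree, path: str | Path, format: str = "newick") -> None:
    """Write a TimeTree as Newick or NEXUS; branch lengths are age
    differences in Myr, and a set origin is encoded as a root-edge length."""
    if format not in ("newick", "nexus"):
        raise ValidationError(f"unknown tree format {format!r}")
    dtree = _to_dendropy(tree)
    kwargs = dict(
        schema=format,
        real_value_format_specifier=".17g",
        unquoted_underscores=True,
        suppress_rooting=False,
    )
    with open(path, "w") as fh:
        fh.write(dtree.as_string(**kwargs))


def read_tree(
    path: str | Path,
    format: str = "newick",
    anchor_age: float | None = None,
    reference_age: float = 0.0,
    age_table: AgeRangeTable | None = None,
) -> TimeTree:
    """Read a rooted bifurcating timetree.

    Node ages are derived from branch lengths plus an anchor: the
    youngest tip (greatest root distance) is placed at ``anchor_age``
    (absolute Ma). When no anchor is given but an ``age_table`` is, the
    midpoint of the youngest tip's stratigraphic range is used; with
    neither, the youngest tip sits at the reference age. A root-edge
    length, if present, becomes the origin age. Polytomies and negative
    branch lengths are rejected.
    """
    if format not in ("newick", "nexus"):
        raise ValidationError(f"unknown tree format {format!r}")
    try:
        dtree = dendropy.Tree.get(
            path=str(path),
            schema=format,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises many parse error types
        raise ValidationError(f"could not parse {format} tree {path}: {exc}") from exc

    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        raise ValidationError(f"tree in {path} is empty")

    # depths from the root, validating branch lengths
    depth: dict[dendropy.Node, float] = {dtree.seed_node: 0.0}
    for dnd in dtree.preorder_node_iter():
        if dnd is dtree.seed_node:
            continue
        bl = dnd.edge.length
        if bl is None:
            bl = 0.0
        if bl < 0:
            raise ValidationError(f"negative branch length {bl} in {path}")
        depth[dnd] = depth[dnd.parent_node] + bl

    max_depth = max(depth[lf] for lf in dtree.leaf_node_iter())

    def leaf_label(dnd) -> str:
        if dnd.taxon is not None and dnd.taxon.label:
            return _norm(dnd.taxon.label)
        if dnd.label:
            return _norm(dnd.label)
        raise ValidationError(f"unlabelled leaf in {path}")

    if anchor_age is None:
        if age_table is not None:
            youngest = max(dtree.leaf_node_iter(), key=lambda lf: depth[lf])
            label = leaf_label(youngest)
            if label not in age_table:
                raise ValidationError(
                    f"youngest tip {label!r} missing from the age table"
                )
            oldest, latest = age_table[label]
            anchor_age = 0.5 * (oldest + latest)
        else:
            anchor_age = reference_age

    def build(dnd) -> Node:
        age_abs = anchor_age + (max_depth - depth[dnd])
        children = dnd.child_nodes()
        if len(children) > 2:
            raise ValidationError(
                f"polytomy in {path}: node with {len(children)} children "
                "(trees must be bifurcating)"
            )
        if not children:
            label = leaf_label(dnd)
        else:
            label = _norm(dnd.label) if dnd.label else (
                _norm(dnd.taxon.label) if dnd.taxon is not None and dnd.taxon.label
                else None
            )
            if len(children) == 1 and label is None:
                raise ValidationError(
                    f"unlabelled unary node in {path}: only sampled-ancestor "
                    "fossils may have a single child"
                )
        node = Node(age=age_abs - reference_age, label=label)
        for dch in children:
            node.add_child(build(dch))
        return node

    root = build(dtree.seed_node)
    if root.age < 0:
        raise ValidationError(
            "tree extends younger than the reference age; check the anchor"
        )
    origin = None
    if dtree.seed_node.edge.length:
        origin = root.age + dtree.seed_node.edge.length
    return TimeTree(root, origin_age=origin, reference_age=reference_age)


# ---------------------------------------------------------------------------
# subsetting
# ---------------------------------------------------------------------------

def prune_taxa(tree: TimeTree, drop: set[str]) -> TimeTree:
    """Remove the named tips; remaining node ages are unchanged and
    unary unlabelled nodes created by the pruning are suppressed
    (labelled sampled-ancestor nodes are kept, possibly becoming tips)."""
    drop = {_norm(t) for t in drop}
    unknown = drop - set(tree.tip_labels)
    if unknown:
        raise ValidationError(f"cannot drop unknown taxa: {sorted(unknown)}")
    if set(tree.tip_labels) <= drop:
        raise ValidationError("cannot drop every tip of the tree")

    def rebuild(nd: Node) -> Node | None:
        if nd.is_leaf:
            if nd.label in drop:
                return None
            return Node(age=nd.age, label=nd.label)
        kept = [c for c in (rebuild(ch) for ch in nd.children) if c is not None]
        if not kept:
            # an SA node whose descendants were all dropped becomes a tip
            if nd.label is not None:
                return Node(age=nd.age, label=nd.label)
            return None
        if len(kept) == 1 and nd.label is None:
            return kept[0]  # suppress the unary pass-through node
        new = Node(age=nd.age, label=nd.label)
        for c in kept:
            new.add_child(c)
        return new

    root = rebuild(tree.root)
    origin = tree.origin_age
    if origin is not None and origin <= root.age:
        origin = None
    bounds = {
        lab: b for lab, b in tree.tip_bounds.items() if lab not in drop
    }
    return TimeTree(
        root,
        origin_age=origin,
        reference_age=tree.reference_age,
        tip_bounds=bounds,
    )


def extract_clade(tree: TimeTree, taxa: set[str]) -> TimeTree:
    """Subtree rooted at the most recent common ancestor of ``taxa``,
    with all of its descendants."""
    taxa = {_norm(t) for t in taxa}
    if len(taxa) < 2:
        raise ValidationError("extract_clade needs at least two taxa")
    unknown = taxa - set(tree.tip_labels)
    if unknown:
        raise ValidationError(f"unknown taxa: {sorted(unknown)}")

    def mrca(nd: Node) -> tuple[Node | None, int]:
        """Deepest node whose subtree holds every target, plus a count."""
        if nd.is_leaf:
            return (None, 1 if nd.label in taxa else 0)
        count = 0
        for ch in nd.children:
            found, c = mrca(ch)
            if found is not None:
                return (found, c)
            count += c
        if count == len(taxa):
            return (nd, count)
        return (None, count)

    anc, _ = mrca(tree.root)
    assert anc is not None

    sub = tree.copy()
    # locate the corresponding node in the copy by the path from the root
    path = []
    nd = anc
    while nd.parent is not None:
        path.append(nd.parent.children.index(nd))
        nd = nd.parent
    node = sub.root
    for idx in reversed(path):
        node = node.children[idx]
    node.parent = None
    labels = {n.label for n in TimeTree(node, reference_age=tree.reference_age).sample_nodes()}
    bounds = {lab: b for lab, b in tree.tip_bounds.items() if lab in labels}
    origin = tree.origin_age if anc is tree.root else None
    return TimeTree(
        node,
        origin_age=origin,
        reference_age=tree.reference_age,
        tip_bounds=bounds,
    )


def attach_tip_constraints(tree: TimeTree, table: AgeRangeTable) -> TimeTree:
    """Attach stratigraphic (oldest, youngest) bounds from an age table
    to every fossil sample of the tree.

    Bounds are converted to the tree's internal coordinate (clamped at 0,
    the reference age). A sample whose current age falls outside its
    bounds is moved to the bound midpoint; equal bounds pin the age.
    Ancestors are then lifted minimally where a moved sample would
    otherwise be older than its parent, keeping the tree valid. Returns
    a new tree; the input is not modified.
    """
    out = tree.copy()
    samples = out.sample_nodes()
    missing = [nd.label for nd in samples if nd.label not in table]
    if missing:
        raise ValidationError(
            f"taxa missing from the age table: {sorted(missing)}"
        )
    ref = out.reference_age
    for nd in samples:
        oldest_abs, youngest_abs = table[nd.label]
        if oldest_abs < ref:
            raise ValidationError(
                f"taxon {nd.label!r} range lies entirely younger than the "
                f"reference age {ref} Ma"
            )
        oldest = oldest_abs - ref
        youngest = max(0.0, youngest_abs - ref)
        out.tip_bounds[nd.label] = (oldest, youngest)
        if not (youngest <= nd.age <= oldest):
            nd.age = 0.5 * (oldest + youngest)

    def lift(nd: Node) -> None:
        for ch in nd.children:
            lift(ch)
        if nd.children:
            nd.age = max([nd.age] + [ch.age for ch in nd.children])

    lift(out.root)
    if out.origin_age is not None and out.origin_age <= out.root.age:
        out.origin_age = out.root.age + 1.0
    out.validate()
    return out
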