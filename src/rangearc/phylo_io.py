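"""Dated trees: reading, validation, and per-node clade enumeration.

Trees are rooted, fully bifurcating, ultrametric chronograms with branch
lengths in Myr.  Node ages (Ma before present) are derived from root-to-tip
path lengths; tips sit at age 0.  The node table drives the age-range
correlation: one record per internal node with its age and the two daughter
clade tip sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["DatedTree", "NodeRecord", "read_tree", "node_table"]

#: default ultrametricity tolerance, relative to tree height (chronogram round-off)
ULTRAMETRIC_RTOL = 1e-6


@dataclass
class DatedTree:
    """A validated, dated, bifurcating ultrametric tree.

    Wraps a :class:`dendropy.Tree`; ``ages`` maps each internal
    :class:`dendropy.Node` to its age in Ma.
    """

    tree: dendropy.Tree
    ages: dict = field(repr=False)

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def root_age(self) -> float:
        return self.ages[self.tree.seed_node]

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_nodes()]

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


@dataclass
class NodeRecord:
    """One internal node of the chronogram, ready for index computation.

    ``tips_left`` / ``tips_right`` are the taxon ids descending from the
    node's two children; arc_stats later fills clade areas, overlap, the
    sympatry and symmetry indexes and the species-level mean/max sympatry.
    """

    node_id: str
    age: float
    tips_left: frozenset[str]
    tips_right: frozenset[str]
    area_left: float | None = None
    area_right: float | None = None
    overlap: float | None = None
    sympatry: float | None = None
    symmetry: float | None = None
    mean_sp_sympatry: float | None = None
    max_sp_sympatry: float | None = None

    def __post_init__(self):
        self.tips_left = frozenset(self.tips_left)
        self.tips_right = frozenset(self.tips_right)
        if not self.tips_left or not self.tips_right:
            raise ValueError(f"node {self.node_id}: empty daughter clade")
        if self.tips_left & self.tips_right:
            raise ValueError(f"node {self.node_id}: daughter clades overlap")

    @property
    def tips(self) -> frozenset[str]:
        return self.tips_left | self.tips_right


def validate_tree(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> DatedTree:
    """Check bifurcation/ultrametricity and compute node ages.

    Raises ``ValueError`` naming the offending node for polytomies, missing
    branch lengths, or root-to-tip depth spread beyond ``rtol`` x tree height.
    """
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 tips")
    for node in tree.preorder_node_iter():
        kids = node.child_nodes()
        if kids and len(kids) != 2:
            label = node.label or node.taxon.label if node.taxon else "<unnamed>"
            raise ValueError(
                f"polytomy (or unifurcation) at node {label!r}: {len(kids)} children"
            )
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("missing branch length on a non-root edge")

    depth: dict = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[node] = depth[node.parent_node] + node.edge.length
    tip_depths = [depth[leaf] for leaf in leaves]
    height = max(tip_depths)
    spread = height - min(tip_depths)
    if height <= 0:
        raise ValueError("tree has zero height")
    if spread > rtol * height:
        raise ValueError(
            f"tree is not ultrametric: root-to-tip depths differ by {spread:g} "
            f"(tolerance {rtol:g} x height {height:g})"
        )
    ages = {node: height - d for node, d in depth.items() if node.child_nodes()}
    for leaf in leaves:
        ages[leaf] = 0.0
    return DatedTree(tree, ages)


def read_tree(path, rtol: float = ULTRAMETRIC_RTOL) -> DatedTree:
    """Read a single newick chronogram and validate it."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True,
        rooting="force-rooted",
    )
    return validate_tree(tree, rtol=rtol)


def parse_tree(newick: str, rtol: float = ULTRAMETRIC_RTOL) -> DatedTree:
    """Parse a newick string and validate it."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        rooting="force-rooted",
    )
    return validate_tree(tree, rtol=rtol)


def _clade_tips(node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def internal_node_ids(t: DatedTree) -> dict:
    """Stable ids for internal nodes: newick label if present, else ``n<rank>``.

    Rank orders nodes by descending age, ties broken by the sorted tip set,
    so ids are reproducible across reads of the same tree.
    """
    internals = [n for n in t.tree.preorder_node_iter() if n.child_nodes()]
    internals.sort(key=lambda n: (-t.ages[n], str(sorted(_clade_tips(n)))))
    return {node: (node.label or f"n{i}") for i, node in enumerate(internals)}


def node_table(t: DatedTree, include_root: bool = True) -> list[NodeRecord]:
    """One NodeRecord per internal node, sorted by descending age.

    The root is included by default; both conventions exist in the
    age-range-correlation literature, so exclusion is a flag rather than a
    policy.
    """
    ids = internal_node_ids(t)
    internals = sorted(ids, key=lambda n: (-t.ages[n], str(sorted(_clade_tips(n)))))
    records = []
    for node in internals:
        if not include_root and node is t.tree.seed_node:
            continue
        left, right = node.child_nodes()
        records.append(
            NodeRecord(
                node_id=ids[node],
                age=t.ages[node],
                tips_left=_clade_tips(left),
                tips_right=_clade_tips(right),
            )
        )
    return records
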