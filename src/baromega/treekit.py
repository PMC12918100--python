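"""Rooted bifurcating phylogenies: Newick I/O and branch bookkeeping.

Every downstream quantity in this package (ancestral states, stochastic-map
weights, per-branch omega) is indexed by branch, and a branch is identified
with its child node.  Node ids are assigned by a deterministic post-order
traversal so that branch identities are stable across runs and joinable
across modules.  A rooted bifurcating tree with ``n`` leaves has ``2n - 1``
nodes and ``2n - 2`` branches (a stem length on the root, if present in the
Newick, is kept but never enumerated as a branch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy
import pandas as pd

__all__ = [
    "TreeError",
    "PhyloNode",
    "PhyloTree",
    "parse_newick",
    "write_newick",
    "count_branches",
]


class TreeError(ValueError):
    """Raised for malformed Newick input or invariant violations."""


@dataclass
class PhyloNode:
    id: int
    label: Optional[str] = None          # leaf label; None for internal nodes
    parent: Optional[int] = None         # parent node id; None for the root
    children: list[int] = field(default_factory=list)
    length: float = 1.0                  # branch length to parent (root: stem)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted, strictly bifurcating tree with post-order node ids.

    ``nodes[i].id == i``; the root has the highest id (``2n - 2``).
    Branches are identified by their child node id.
    """

    def __init__(self, nodes: list[PhyloNode], root_id: int, root_stem: Optional[float] = None):
        self.nodes = nodes
        self.root_id = root_id
        self.root_stem = root_stem
        self._validate()

    # -- construction -----------------------------------------------------

    def _validate(self) -> None:
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1 or roots[0].id != self.root_id:
            raise TreeError("tree must have exactly one root")
        labels = []
        for n in self.nodes:
            if n.children and len(n.children) != 2:
                raise TreeError(
                    f"not bifurcating: node {n.id} has {len(n.children)} children"
                )
            if n.is_leaf:
                if not n.label:
                    raise TreeError(f"leaf {n.id} has an empty label")
                labels.append(n.label)
            if n.parent is not None and n.length < 0:
                raise TreeError(f"negative branch length on node {n.id}")
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dups}")
        n_leaves = len(labels)
        if len(self.nodes) != 2 * n_leaves - 1:
            raise TreeError("node count inconsistent with a bifurcating tree")

    # -- traversal --------------------------------------------------------

    @property
    def root(self) -> PhyloNode:
        return self.nodes[self.root_id]

    @property
    def leaves(self) -> list[PhyloNode]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes if n.is_leaf)

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.postorder() if n.is_leaf]

    def postorder(self) -> Iterator[PhyloNode]:
        """Yield nodes children-before-parents (ids are already in this order)."""
        return iter(self.nodes)

    def preorder(self) -> Iterator[PhyloNode]:
        return reversed(self.nodes)

    def branches(self) -> list[PhyloNode]:
        """All non-root nodes; each identifies the branch to its parent."""
        return [n for n in self.nodes if n.parent is not None]

    def branch_table(self) -> pd.DataFrame:
        rows = [
            {
                "branch_id": n.id,
                "parent_node": n.parent,
                "child_node": n.id,
                "length": n.length,
            }
            for n in self.branches()
        ]
        return pd.DataFrame(rows, columns=["branch_id", "parent_node", "child_node", "length"])

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def to_newick(self) -> str:
        return write_newick(self)


def _fmt_len(x: float) -> str:
    return format(float(x), ".10g")


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted bifurcating Newick tree.

    Branch lengths default to 1.0 when absent.  Polytomies, duplicate leaf
    labels, negative lengths and malformed input raise :class:`TreeError`.
    """
    if not text.strip().endswith(";"):
        raise TreeError("Newick string must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as exc:  # dendropy raises a mix of error types
        raise TreeError(f"malformed Newick: {exc}") from exc

    nodes: list[PhyloNode] = []
    idx: dict[int, int] = {}  # id(dendropy node) -> our id
    for dnode in dtree.seed_node.postorder_iter():
        nid = len(nodes)
        idx[id(dnode)] = nid
        label = dnode.taxon.label if dnode.taxon is not None else None
        length = dnode.edge.length
        node = PhyloNode(
            id=nid,
            label=label if dnode.is_leaf() else None,
            length=1.0 if length is None else float(length),
        )
        for child in dnode.child_nodes():
            cid = idx[id(child)]
            node.children.append(cid)
            nodes[cid].parent = nid
        nodes.append(node)
    root_id = len(nodes) - 1
    stem = dtree.seed_node.edge.length
    nodes[root_id].length = 0.0 if stem is None else float(stem)
    root_stem = None if stem is None else float(stem)
    if nodes[root_id].length < 0:
        raise TreeError("negative root stem length")
    return PhyloTree(nodes, root_id, root_stem=root_stem)


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick; lengths printed to 10 significant digits."""

    def rec(node: PhyloNode) -> str:
        if node.is_leaf:
            body = node.label
        else:
            body = "(" + ",".join(rec(tree.nodes[c]) for c in node.children) + ")"
        if node.parent is None:
            if tree.root_stem is not None:
                return f"{body}:{_fmt_len(tree.root_stem)}"
            return body
        return f"{body}:{_fmt_len(node.length)}"

    return rec(tree.root) + ";"


def count_branches(tree: PhyloTree) -> int:
    """Number of edges, root stem excluded: 2n - 2 for n leaves."""
    return len(tree.branches())
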