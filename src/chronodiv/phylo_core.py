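"""Time-calibrated phylogenies and the structures derived from them.

A :class:`TimeTree` is a rooted, binary, ultrametric tree whose node ages
are measured in million years (My) before the present; tips sit at age 0
and ages increase into the past.  Every downstream computation — the
birth-death likelihood, lineage-through-time counts, tip-rate statistics,
Brownian trait simulation — consumes the arrays cached here rather than
re-walking the tree.

Trees are read and written through dendropy; this module owns validation:
polytomies are rejected (the likelihood assumes a binary reconstructed
tree), missing or non-positive branch lengths are rejected, and trees
whose root-to-tip spread exceeds ``1e-6 x crown age`` are rejected rather
than silently stretched, because silent repair biases branching times.
A single unifurcation at the root (a stem edge) is tolerated: branching
times and the likelihood are defined on the crown tree, while per-tip
path statistics (equal-splits) include the stem edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import TreeError

#: relative root-to-tip spread above which a tree is declared non-ultrametric
ULTRAMETRIC_RTOL = 1e-6


@dataclass
class TimeTree:
    """Validated ultrametric time tree plus cached node-age arrays.

    Nodes are indexed 0..n_nodes-1 in preorder; tips first carry labels in
    ``tip_labels`` (tip i is node index ``tip_index[i]``).  ``ages`` holds
    My before present for every node, ``parent`` the parent index (-1 for
    the root), ``edge_length`` the length of the edge above each node
    (nan for the root).
    """

    newick: str
    sampling_fraction: float = 1.0
    name: str = ""

    # filled by __post_init__
    tip_labels: list[str] = field(init=False)
    ages: np.ndarray = field(init=False)
    parent: np.ndarray = field(init=False)
    children: list[list[int]] = field(init=False)
    edge_length: np.ndarray = field(init=False)
    tip_index: np.ndarray = field(init=False)
    root_index: int = field(init=False)
    crown_index: int = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.sampling_fraction <= 1.0:
            raise TreeError(
                f"sampling fraction must be in (0, 1], got {self.sampling_fraction}"
            )
        tree = dendropy.Tree.get(
            data=self.newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        self._dendropy_tree = tree
        self._index_and_validate(tree)

    # ------------------------------------------------------------------
    def _index_and_validate(self, tree: dendropy.Tree) -> None:
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n_nodes = len(nodes)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        depth = np.zeros(n_nodes)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        labels: list[str] = []
        tip_idx: list[int] = []
        edge_len = np.full(n_nodes, np.nan)

        root = nodes[0]
        for nd in nodes:
            i = index[id(nd)]
            kids = nd.child_nodes()
            for ch in kids:
                j = index[id(ch)]
                parent[j] = i
                children[i].append(j)
                if ch.edge.length is None:
                    raise TreeError(
                        f"missing branch length on the edge above node {j}"
                    )
                if ch.edge.length <= 0:
                    raise TreeError(
                        f"non-positive branch length {ch.edge.length} above node {j}"
                    )
                edge_len[j] = ch.edge.length
                depth[j] = depth[i] + ch.edge.length
            if len(kids) == 0:
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeError(f"unlabeled tip at node {index[id(nd)]}")
                labels.append(nd.taxon.label)
                tip_idx.append(i)
            elif len(kids) == 1 and nd is not root:
                raise TreeError(f"unifurcation at internal node {i}")
            elif len(kids) > 2:
                label = nd.taxon.label if nd.taxon else f"node {i}"
                raise TreeError(f"polytomy ({len(kids)}-furcation) at {label}")

        if len(labels) < 2:
            raise TreeError("a time tree needs at least 2 tips")
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels")

        tip_idx_arr = np.asarray(tip_idx, dtype=np.int64)
        tip_depths = depth[tip_idx_arr]
        tree_height = float(tip_depths.max())
        spread = float(tip_depths.max() - tip_depths.min())
        if spread > ULTRAMETRIC_RTOL * tree_height:
            raise TreeError(
                f"tree is not ultrametric: root-to-tip spread {spread:.6g} "
                f"exceeds {ULTRAMETRIC_RTOL:g} x height {tree_height:.6g}"
            )

        ages = tree_height - depth
        ages[tip_idx_arr] = 0.0  # absorb sub-tolerance jitter

        self.tip_labels = labels
        self.ages = ages
        self.parent = parent
        self.children = children
        self.edge_length = edge_len
        self.tip_index = tip_idx_arr
        self.root_index = 0
        # crown node: first bifurcation walking down from the root (the root
        # itself unless a stem unifurcation is present)
        crown = 0
        while len(children[crown]) == 1:
            crown = children[crown][0]
        self.crown_index = crown

    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def crown_age(self) -> float:
        return float(self.ages[self.crown_index])

    @property
    def internal_ages(self) -> np.ndarray:
        """Ages of the bifurcating nodes of the crown tree (unsorted)."""
        is_internal = np.array([len(c) == 2 for c in self.children])
        return self.ages[is_internal]

    def write_newick(self, precision: int = 12) -> str:
        """Serialize as Newick with branch lengths at ``precision`` significant digits."""
        out = self._dendropy_tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=f".{precision}g",
        )
        return out.strip()

    def total_branch_length(self) -> float:
        return float(np.nansum(self.edge_length))

    def vcv(self) -> np.ndarray:
        """Brownian-motion covariance among tips: shared path length from
        the crown node, ordered like ``tip_labels``.  O(n^2)."""
        n = self.n_tips
        crown_age = self.crown_age
        # depth below crown node for every node
        cov = np.zeros((n, n))
        tip_of_node: dict[int, list[int]] = {}
        # postorder accumulation of tip sets
        post = self._postorder(self.crown_index)
        tip_pos = {int(node): i for i, node in enumerate(self.tip_index)}
        for nd in post:
            kids = self.children[nd]
            if not kids:
                tip_of_node[nd] = [tip_pos[nd]]
                cov[tip_pos[nd], tip_pos[nd]] = crown_age
            else:
                sets = [tip_of_node.pop(k) for k in kids]
                shared = crown_age - self.ages[nd]
                for a_i, a in enumerate(sets):
                    for b in sets[a_i + 1 :]:
                        for ti in a:
                            cov[ti, b] = shared
                            cov[np.asarray(b), ti] = shared
                merged: list[int] = []
                for s in sets:
                    merged.extend(s)
                tip_of_node[nd] = merged
        return cov

    def _postorder(self, start: int) -> list[int]:
        out: list[int] = []
        stack = [start]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(self.children[nd])
        return out[::-1]

    def edges(self, crown_only: bool = True) -> np.ndarray:
        """(child_age, parent_age) pairs, one row per edge.

        With ``crown_only`` the stem edge (if any) is excluded, which is
        what the reconstructed-process likelihood integrates over.
        """
        rows = []
        for j in range(len(self.parent)):
            if self.parent[j] < 0:
                continue
            if crown_only and j == self.crown_index:
                continue  # stem edge
            rows.append((self.ages[j], self.ages[self.parent[j]]))
        return np.asarray(rows, dtype=float)


# ----------------------------------------------------------------------
def parse_newick(text: str, f: float = 1.0, name: str = "") -> TimeTree:
    """Parse a single Newick tree into a validated :class:`TimeTree`.

    Parameters
    ----------
    text : str
        Newick string (quoted labels allowed, internal labels ignored).
    f : float
        Global sampling fraction in (0, 1]: the probability that an extant
        species appears in the tree.
    """
    return TimeTree(newick=text, sampling_fraction=f, name=name)


def read_newick_file(path: str, f: float = 1.0) -> TimeTree:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read(), f=f, name=path)


def branching_times(tree: TimeTree) -> np.ndarray:
    """Internal-node ages of the crown tree, descending; length n_tips - 1,
    first element equal to the crown age."""
    bt = np.sort(tree.internal_ages)[::-1]
    assert len(bt) == tree.n_tips - 1
    return bt


def ltt_curve(tree: TimeTree, grid: np.ndarray) -> np.ndarray:
    """Number of reconstructed lineages extant at each query age.

    The count is 2 at the crown age (the crown split has happened) and
    n_tips at the present; it is non-increasing with age.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < 0 or grid.max() > tree.crown_age * (1 + 1e-12)):
        raise TreeError(
            f"LTT grid must lie within [0, {tree.crown_age}], "
            f"got [{grid.min()}, {grid.max()}]"
        )
    bt = branching_times(tree)
    # lineages at age a: 1 + number of branching events at or older than a
    return 1 + np.sum(bt[None, :] >= grid[:, None], axis=1)
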