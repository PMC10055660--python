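"""Differentiation tree, cell placement, and cell-identity-factor blocks.

The cell population is controlled by a differentiation tree (Newick text).
In continuous mode cells are placed uniformly along the tree's branches and
their differential CIFs are generated by a Brownian walk along the tree, so
cells sharing ancestry share walk increments and diverge after their split.
In discrete mode only the tree tips are used: each tip gets a
Gaussian-sampled anchor and cells of that type are jittered around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

__all__ = [
    "DifferentiationTree",
    "CellAssignment",
    "CifBlock",
    "parse_newick",
    "builtin_tree",
    "assign_cells",
    "predecessor_order",
    "generate_diff_cif",
    "generate_nd_cif",
]

#: example trees with 1, 3 and 5 tips (linear, small tree, larger tree)
_BUILTIN_TREES = {
    "phyla1": "(A:1)root;",
    "phyla3": "((A:1,B:1)AB:1,C:1.5)root;",
    "phyla5": "(((A:1,B:1)AB:1,C:1.5)ABC:0.5,(D:1,E:1)DE:1.5)root;",
}


@dataclass(frozen=True)
class TreeEdge:
    parent: str
    child: str
    length: float


class DifferentiationTree:
    """A rooted tree with positive branch lengths, stored edge-wise.

    ``edges`` are in preorder (parents before children), which the
    Brownian-walk generator and the sequential expression simulation rely
    on.
    """

    def __init__(self, edges: Sequence[TreeEdge], root: str):
        if not edges:
            raise ValueError("tree must have at least one edge")
        self.edges: List[TreeEdge] = list(edges)
        self.root = root
        for e in self.edges:
            if not (e.length > 0):
                raise ValueError(
                    f"branch {e.parent}->{e.child} must have positive length")
        children: Dict[str, List[str]] = {}
        self._parent_edge: Dict[str, int] = {}
        for i, e in enumerate(self.edges):
            children.setdefault(e.parent, []).append(e.child)
            if e.child in self._parent_edge:
                raise ValueError(f"node {e.child} has two parents")
            self._parent_edge[e.child] = i
        self._children = children
        self.tips: List[str] = [e.child for e in self.edges
                                if e.child not in children]
        # depth of every node (distance from the root)
        self._depth: Dict[str, float] = {root: 0.0}
        for e in self.edges:
            self._depth[e.child] = self._depth[e.parent] + e.length

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def total_length(self) -> float:
        return float(sum(e.length for e in self.edges))

    @property
    def max_depth(self) -> float:
        return max(self._depth[t] for t in self.tips)

    def depth(self, node: str) -> float:
        return self._depth[node]

    def parent_edge_index(self, node: str) -> Optional[int]:
        return self._parent_edge.get(node)

    def path_to_tip(self, tip: str) -> List[int]:
        """Edge indices on the root-to-tip path, root side first."""
        path = []
        node = tip
        while node != self.root:
            idx = self._parent_edge[node]
            path.append(idx)
            node = self.edges[idx].parent
        return path[::-1]

    def geodesic(self, point_a: Tuple[int, float],
                 point_b: Tuple[int, float]) -> float:
        """Tree distance between two points given as (edge index, offset)."""
        da = self._depth[self.edges[point_a[0]].parent] + point_a[1]
        db = self._depth[self.edges[point_b[0]].parent] + point_b[1]
        shared = self._shared_path_length(point_a, point_b)
        return da + db - 2.0 * shared

    def _shared_path_length(self, point_a, point_b) -> float:
        ia, offa = point_a
        ib, offb = point_b
        anc_a = {}
        node = self.edges[ia].child
        # ancestor edges of a (full), plus partial on its own edge
        own_a = {ia: offa}
        for idx in self.path_to_tip_edge(ia):
            own_a.setdefault(idx, self.edges[idx].length)
        own_b = {ib: offb}
        for idx in self.path_to_tip_edge(ib):
            own_b.setdefault(idx, self.edges[idx].length)
        shared = 0.0
        for idx, la in own_a.items():
            if idx in own_b:
                shared += min(la, own_b[idx])
        return shared

    def path_to_tip_edge(self, edge_idx: int) -> List[int]:
        """Edge indices strictly above ``edge_idx`` (root side)."""
        path = []
        node = self.edges[edge_idx].parent
        while node != self.root:
            idx = self._parent_edge[node]
            path.append(idx)
            node = self.edges[idx].parent
        return path


def parse_newick(text: str) -> DifferentiationTree:
    """Parse a Newick string (or file content) into a tree.

    Unlabeled internal nodes are auto-named ``node_<i>`` in preorder, so the
    naming is deterministic for a given topology.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=False)
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick string: {exc}") from exc
    counter = [0]

    def name_of(node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        if node.label:
            return node.label
        counter[0] += 1
        label = f"node_{counter[0]}"
        node.label = label
        return label

    root = tree.seed_node
    root_name = name_of(root)
    edges: List[TreeEdge] = []

    def walk(node, node_name):
        for child in node.child_nodes():
            child_name = name_of(child)
            length = child.edge.length
            if length is None:
                length = 1.0
            edges.append(TreeEdge(node_name, child_name, float(length)))
            walk(child, child_name)

    walk(root, root_name)
    if not edges:
        raise ValueError("tree has no branches")
    return DifferentiationTree(edges, root_name)


def builtin_tree(name: str) -> DifferentiationTree:
    """Return one of the packaged example trees (phyla1/phyla3/phyla5)."""
    key = name.lower()
    if key not in _BUILTIN_TREES:
        raise ValueError(f"unknown tree '{name}'; expected one of "
                         f"{sorted(_BUILTIN_TREES)}")
    return parse_newick(_BUILTIN_TREES[key])


@dataclass
class CellAssignment:
    """Per-cell position on the differentiation tree."""

    branch: np.ndarray          # edge index per cell
    offset: np.ndarray          # distance from the branch's parent node
    pseudotime: np.ndarray      # distance from the root
    type_label: np.ndarray      # node id (tip id in discrete mode)
    discrete: bool

    @property
    def n_cell(self) -> int:
        return self.branch.size

    def depth_fraction(self, tree: DifferentiationTree) -> np.ndarray:
        lengths = np.array([tree.edges[b].length for b in self.branch])
        return self.offset / lengths


def assign_cells(tree: DifferentiationTree, n_cell: int, discrete: bool,
                 rng: np.random.Generator) -> CellAssignment:
    """Place cells on the tree.

    Continuous mode: uniform over total branch length. Discrete mode: cells
    partitioned near-evenly across tips; remainder cells go to tips in
    deterministic tip order.
    """
    if n_cell < 1:
        raise ValueError("n_cell must be >= 1")
    if discrete:
        n_tips = tree.n_tips
        base = n_cell // n_tips
        rem = n_cell % n_tips
        branch = np.empty(n_cell, dtype=int)
        offset = np.empty(n_cell)
        labels = np.empty(n_cell, dtype=object)
        pos = 0
        for i, tip in enumerate(tree.tips):
            count = base + (1 if i < rem else 0)
            e_idx = tree.parent_edge_index(tip)
            length = tree.edges[e_idx].length
            branch[pos:pos + count] = e_idx
            offset[pos:pos + count] = length
            labels[pos:pos + count] = tip
            pos += count
        pt = np.array([tree.depth(lbl) for lbl in labels], dtype=float)
        return CellAssignment(branch, offset, pt, labels.astype(str), True)

    lengths = np.array([e.length for e in tree.edges])
    probs = lengths / lengths.sum()
    branch = rng.choice(len(tree.edges), size=n_cell, p=probs)
    # u in (0, 1] so pseudotime lies in (0, total depth]
    u = 1.0 - rng.random(n_cell)
    offset = u * lengths[branch]
    parent_depth = np.array([tree.depth(tree.edges[b].parent)
                             for b in branch])
    pseudotime = parent_depth + offset
    labels = np.array([tree.edges[b].child for b in branch], dtype=str)
    return CellAssignment(branch, offset, pseudotime, labels, False)


def predecessor_order(tree: DifferentiationTree,
                      assignment: CellAssignment
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Simulation order and per-cell predecessor for sequential effects.

    Cells are visited branch by branch in preorder, shallow to deep within
    a branch. A cell's predecessor is its nearest upstream cell on the same
    branch; the first cell of a branch inherits from the deepest cell of the
    nearest ancestor branch that carries cells. Cells with no upstream cell
    get predecessor -1 (Gaussian-initialised state).
    """
    n = assignment.n_cell
    order: List[int] = []
    pred = np.full(n, -1, dtype=int)
    cells_by_edge: Dict[int, List[int]] = {}
    for c in range(n):
        cells_by_edge.setdefault(int(assignment.branch[c]), []).append(c)
    deepest_on_edge: Dict[int, int] = {}
    for e_idx in range(len(tree.edges)):
        cells = cells_by_edge.get(e_idx, [])
        if not cells:
            continue
        cells = sorted(cells, key=lambda c: (assignment.offset[c], c))
        upstream = _nearest_upstream_cell(tree, e_idx, deepest_on_edge)
        for c in cells:
            pred[c] = upstream
            order.append(c)
            upstream = c
        deepest_on_edge[e_idx] = cells[-1]
    return np.array(order, dtype=int), pred


def _nearest_upstream_cell(tree: DifferentiationTree, edge_idx: int,
                           deepest_on_edge: Dict[int, int]) -> int:
    for anc in tree.path_to_tip_edge(edge_idx):
        if anc in deepest_on_edge:
            return deepest_on_edge[anc]
    return -1


@dataclass
class CifBlock:
    """One segment of the cell-identity-factor matrix (cells x width)."""

    matrix: np.ndarray
    segment: str                # nd | diff | tf | lig
    parameter: Optional[str] = None  # kon | koff | s

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


def generate_diff_cif(tree: DifferentiationTree, assignment: CellAssignment,
                      n_diff: int, sigma_cif: float, discrete: bool,
                      rng: np.random.Generator,
                      parameter: Optional[str] = None) -> CifBlock:
    """Differential CIF block.

    Continuous: each dimension is a Brownian motion along the tree with
    per-unit-length standard deviation ``sigma_cif``; cells on the same
    lineage share the increments of their common path, so the covariance of
    two cells is proportional to their shared root-path length.
    Discrete: one N(1, 1) anchor per tip, cells jittered by N(0, sigma_cif).
    """
    if n_diff < 1:
        raise ValueError("n_diff must be >= 1")
    n = assignment.n_cell
    out = np.empty((n, n_diff))
    if discrete:
        # Anchors are tip values of a Brownian walk with fixed unit
        # per-length scale: the tree sets the between-cluster geometry,
        # while sigma_cif controls only the within-type jitter. (If the
        # anchor walk also scaled with sigma_cif the structure would be
        # scale-free and sigma_cif could not tighten cluster boundaries.)
        anchors = 1.0 + _tip_anchor_walk(tree, n_diff, 1.0, rng)
        tip_index = {t: i for i, t in enumerate(tree.tips)}
        rows = np.array([tip_index[t] for t in assignment.type_label])
        out = anchors[rows] + rng.normal(0.0, sigma_cif, size=(n, n_diff))
        return CifBlock(out, "diff", parameter)

    # Brownian walk: visit edges in preorder; within an edge, accumulate
    # increments between consecutive cell positions (and down to the child
    # node), starting from the parent node's value.
    node_val: Dict[str, np.ndarray] = {tree.root: np.zeros(n_diff)}
    cells_by_edge: Dict[int, List[int]] = {}
    for c in range(n):
        cells_by_edge.setdefault(int(assignment.branch[c]), []).append(c)
    for e_idx, edge in enumerate(tree.edges):
        cells = sorted(cells_by_edge.get(e_idx, []),
                       key=lambda c: (assignment.offset[c], c))
        positions = [assignment.offset[c] for c in cells] + [edge.length]
        gaps = np.diff([0.0] + positions)
        incs = rng.normal(size=(len(gaps), n_diff)) \
            * sigma_cif * np.sqrt(gaps)[:, None]
        walk = node_val[edge.parent] + np.cumsum(incs, axis=0)
        for k, c in enumerate(cells):
            out[c] = walk[k]
        node_val[edge.child] = walk[-1]
    return CifBlock(out, "diff", parameter)


def _tip_anchor_walk(tree: DifferentiationTree, n_diff: int,
                     sigma_cif: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Brownian values at the tree tips (n_tips x n_diff): increments of
    variance sigma_cif^2 per unit branch length, shared along common
    ancestry."""
    node_val: Dict[str, np.ndarray] = {tree.root: np.zeros(n_diff)}
    for edge in tree.edges:
        inc = rng.normal(size=n_diff) * sigma_cif * np.sqrt(edge.length)
        node_val[edge.child] = node_val[edge.parent] + inc
    return np.stack([node_val[t] for t in tree.tips])


def generate_nd_cif(n_cell: int, n_nd: int, sigma_cif: float,
                    rng: np.random.Generator,
                    parameter: Optional[str] = None) -> CifBlock:
    """Non-differential CIF block: i.i.d. N(1, sigma_cif) entries.

    The unit mean keeps the CIF x GIV products centered on positive mass;
    rank scaling downstream makes the location choice largely immaterial.
    """
    if n_nd < 0:
        raise ValueError("n_nd must be >= 0")
    return CifBlock(rng.normal(1.0, sigma_cif, size=(n_cell, n_nd)),
                    "nd", parameter)
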