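"""Energy landscape construction over the N-dimensional hypercube.

Every one of the 2^N activity patterns gets an energy from a fitted
pairwise MEM.  States whose energy is strictly below all N single-bit-flip
(Hamming-1) neighbors are local minima — the stable connectivity states.
Steepest-descent dynamics partition the hypercube into basins, and the
minimax barrier between two states is the smallest achievable value of the
maximum energy along any connecting path.  The disconnectivity tree is the
dendrogram over local minima whose merge heights are those barriers; it is
built by an ascending-energy union-find sweep, which is equivalent to
running a Dijkstra variant whose path cost is the running maximum energy
(both are computed here, and their agreement is a test oracle).

Ties are broken toward the lowest state index throughout, and a plateau
(a state with an equal-energy neighbor) is never a minimum.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    MEMParams,
    _check_capacity,
    all_patterns,
    decode_state,
    pattern_energies,
)


def enumerate_energies(params: MEMParams) -> np.ndarray:
    """Energy of every state, indexed by state offset (state index - 1)."""
    return pattern_energies(all_patterns(params.n_regions), params)


def _check_energies(energies: np.ndarray, n_regions: int) -> np.ndarray:
    energies = np.asarray(energies, dtype=float)
    _check_capacity(n_regions)
    if energies.shape != (1 << n_regions,):
        raise ValueError(
            f"energies must have length 2^{n_regions} = {1 << n_regions}, "
            f"got {energies.shape}"
        )
    return energies


def find_local_minima(energies: np.ndarray, n_regions: int) -> List[int]:
    """1-based indices of states strictly below all N Hamming-1 neighbors."""
    energies = _check_energies(energies, n_regions)
    offsets = np.arange(energies.size)
    is_min = np.ones(energies.size, dtype=bool)
    for k in range(n_regions):
        is_min &= energies < energies[offsets ^ (1 << k)]
    return [int(o) + 1 for o in np.flatnonzero(is_min)]


def assign_basins(energies: np.ndarray, n_regions: int) -> np.ndarray:
    """Steepest-descent basin label (a 1-based minimum index) for every state.

    From each state move to the lowest-energy strictly lower neighbor
    (ties to the lowest state index) until none exists; entry ``s - 1`` of
    the result is the terminal local minimum of state ``s``.
    """
    energies = _check_energies(energies, n_regions)
    size = energies.size
    offsets = np.arange(size)
    best_e = energies.copy()
    target = offsets.copy()
    for k in range(n_regions):
        nb = offsets ^ (1 << k)
        ne = energies[nb]
        lower = ne < best_e
        tie = (ne == best_e) & (nb < target) & (best_e < energies)
        take = lower | tie
        best_e = np.where(take, ne, best_e)
        target = np.where(take, nb, target)
    # pointer doubling until every chain reaches its fixed point
    while not np.array_equal(target, target[target]):
        target = target[target]
    return target + 1


def minimax_barrier(energies: np.ndarray, n_regions: int, a: int, b: int) -> float:
    """min over hypercube paths a -> b of the max energy along the path.

    Endpoints are included in the maximum, so barrier(a, a) = E(a) and
    barrier(a, b) >= max(E(a), E(b)).  Computed with a Dijkstra variant
    whose accumulated path cost is the running maximum energy.
    """
    energies = _check_energies(energies, n_regions)
    size = energies.size
    for s in (a, b):
        if not 1 <= s <= size:
            raise ValueError(f"state index {s} outside [1, {size}]")
    start, goal = a - 1, b - 1
    best = np.full(size, np.inf)
    best[start] = energies[start]
    heap = [(energies[start], start)]
    while heap:
        cost, u = heapq.heappop(heap)
        if u == goal:
            return float(cost)
        if cost > best[u]:
            continue
        for k in range(n_regions):
            v = u ^ (1 << k)
            new_cost = max(cost, energies[v])
            if new_cost < best[v]:
                best[v] = new_cost
                heapq.heappush(heap, (new_cost, v))
    raise AssertionError("hypercube is connected; unreachable")


# --------------------------------------------------------------------------
# landscape container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyLandscape:
    """Exhaustive landscape: energies, local minima, and basin assignment."""

    energies: np.ndarray            # length 2^N, indexed by state offset
    params: MEMParams
    local_minima: Tuple[int, ...]   # 1-based, ascending
    basin_of: np.ndarray            # entry s-1 = 1-based minimum for state s

    @property
    def n_regions(self) -> int:
        return self.params.n_regions


def build_landscape(params: MEMParams) -> EnergyLandscape:
    energies = enumerate_energies(params)
    n = params.n_regions
    minima = find_local_minima(energies, n)
    basins = assign_basins(energies, n)
    return EnergyLandscape(
        energies=energies,
        params=params,
        local_minima=tuple(minima),
        basin_of=basins,
    )


# --------------------------------------------------------------------------
# disconnectivity tree
# --------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A node of the disconnectivity tree.

    Leaves carry a local-minimum state and its energy as ``height``;
    internal nodes carry the barrier energy at which their children's
    basins first connect.
    """

    node_id: int
    height: float
    children: Tuple[int, ...] = ()
    parent: Optional[int] = None
    state: Optional[int] = None     # 1-based state index; None for internal

    @property
    def is_leaf(self) -> bool:
        return self.state is not None


@dataclass
class DisconnectivityTree:
    nodes: List[TreeNode]
    root: int

    @property
    def leaves(self) -> List[TreeNode]:
        return [nd for nd in self.nodes if nd.is_leaf]

    def leaf_for_state(self, state: int) -> TreeNode:
        for nd in self.nodes:
            if nd.state == state:
                return nd
        raise KeyError(f"state {state} is not a leaf of this tree")

    def barrier_between(self, a: int, b: int) -> float:
        """Barrier energy at the lowest common ancestor of two leaf states."""
        leaf_a, leaf_b = self.leaf_for_state(a), self.leaf_for_state(b)
        if a == b:
            return leaf_a.height
        ancestors = set()
        node = leaf_a
        while node is not None:
            ancestors.add(node.node_id)
            node = self.nodes[node.parent] if node.parent is not None else None
        node = leaf_b
        while node is not None:
            if node.node_id in ancestors:
                return node.height
            node = self.nodes[node.parent] if node.parent is not None else None
        raise AssertionError("tree has a single root; unreachable")

    # -- exports ----------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string; leaves are S<state>, branch lengths are barrier drops."""

        def render(node: TreeNode, parent_height: Optional[float]) -> str:
            length = (
                "" if parent_height is None
                else f":{parent_height - node.height:.6g}"
            )
            if node.is_leaf:
                return f"S{node.state}{length}"
            inner = ",".join(
                render(self.nodes[c], node.height) for c in node.children
            )
            return f"({inner})B{node.height:.6g}{length}"

        return render(self.nodes[self.root], None) + ";"

    def to_text(self) -> str:
        """Indented-text dendrogram."""
        lines: List[str] = []

        def render(node: TreeNode, depth: int) -> None:
            pad = "  " * depth
            if node.is_leaf:
                lines.append(
                    f"{pad}state {node.state} (energy {node.height:.6g})"
                )
            else:
                lines.append(f"{pad}barrier {node.height:.6g}")
                for c in node.children:
                    render(self.nodes[c], depth + 1)

        render(self.nodes[self.root], 0)
        return "\n".join(lines)


def build_disconnectivity_tree(landscape: EnergyLandscape) -> DisconnectivityTree:
    """Dendrogram of local minima from an ascending-energy union-find sweep.

    States are activated in order of increasing energy (ties toward the
    lower index) and merged with already-active Hamming neighbors.  When
    components that each contain a local minimum join, an internal node is
    recorded at the activating state's energy; for any two leaves, the
    height of their lowest common ancestor then equals the minimax barrier
    between them.
    """
    energies = landscape.energies
    n = landscape.n_regions
    size = energies.size
    minima = set(landscape.local_minima)
    if not minima:
        raise ValueError("landscape has no local minima")

    nodes: List[TreeNode] = []
    leaf_node: Dict[int, int] = {}
    for s in landscape.local_minima:  # ascending state index
        node = TreeNode(node_id=len(nodes), height=float(energies[s - 1]), state=s)
        nodes.append(node)
        leaf_node[s] = node.node_id

    uf_parent = np.arange(size)

    def find(x: int) -> int:
        while uf_parent[x] != x:
            uf_parent[x] = uf_parent[uf_parent[x]]
            x = uf_parent[x]
        return x

    cluster_node: Dict[int, int] = {}   # uf root -> tree node id
    active = np.zeros(size, dtype=bool)
    order = np.lexsort((np.arange(size), energies))
    for offset in order:
        offset = int(offset)
        active[offset] = True
        state = offset + 1
        root = find(offset)
        if state in minima:
            cluster_node[root] = leaf_node[state]
        merged_tree_nodes: List[int] = []
        if root in cluster_node:
            merged_tree_nodes.append(cluster_node[root])
        for k in range(n):
            nb = offset ^ (1 << k)
            if not active[nb]:
                continue
            nb_root = find(nb)
            if nb_root == root:
                continue
            if nb_root in cluster_node:
                merged_tree_nodes.append(cluster_node.pop(nb_root))
            cluster_node.pop(root, None)
            uf_parent[nb_root] = root
            # nb_root may have been re-rooted; normalize
            root = find(offset)
        if len(merged_tree_nodes) >= 2:
            barrier = float(energies[offset])
            internal = TreeNode(
                node_id=len(nodes),
                height=barrier,
                children=tuple(sorted(merged_tree_nodes)),
            )
            nodes.append(internal)
            for c in merged_tree_nodes:
                nodes[c].parent = internal.node_id
            cluster_node[root] = internal.node_id
        elif merged_tree_nodes:
            cluster_node[root] = merged_tree_nodes[0]

    assert len(cluster_node) == 1, "sweep must end with one component"
    root_id = next(iter(cluster_node.values()))
    return DisconnectivityTree(nodes=nodes, root=root_id)


# --------------------------------------------------------------------------
# tabular exports
# --------------------------------------------------------------------------

def _pattern_string(pattern: np.ndarray) -> str:
    return "".join("+" if x > 0 else "-" for x in pattern)


def minima_table(
    landscape: EnergyLandscape, roi_names: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Local minima as a table: state index, energy, pattern, per-ROI activity."""
    n = landscape.n_regions
    names = list(roi_names) if roi_names is not None else [
        f"roi{i + 1}" for i in range(n)
    ]
    rows = []
    for s in landscape.local_minima:
        pattern = decode_state(s, n)
        row = {
            "state": s,
            "energy": float(landscape.energies[s - 1]),
            "pattern": _pattern_string(pattern),
        }
        row.update({name: int(v) for name, v in zip(names, pattern)})
        rows.append(row)
    return pd.DataFrame(rows)


def activity_pattern_matrix(
    landscape: EnergyLandscape, roi_names: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """ROIs x local-minima ±1 matrix (the activity-pattern panel of the figures)."""
    n = landscape.n_regions
    names = list(roi_names) if roi_names is not None else [
        f"roi{i + 1}" for i in range(n)
    ]
    cols = {
        str(s): decode_state(s, n).astype(int) for s in landscape.local_minima
    }
    return pd.DataFrame(cols, index=names)


def plot_activity_patterns(landscape: EnergyLandscape, roi_names=None, ax=None):
    """Heatmap of the ROIs x minima activity-pattern matrix (optional)."""
    import matplotlib.pyplot as plt

    mat = activity_pattern_matrix(landscape, roi_names)
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.4 * mat.shape[1], 1 + 0.3 * mat.shape[0]))
    ax.imshow(mat.values, cmap="gray_r", aspect="auto", vmin=-1, vmax=1)
    ax.set_xticks(range(mat.shape[1]), mat.columns)
    ax.set_yticks(range(mat.shape[0]), mat.index)
    ax.set_xlabel("local minimum (state index)")
    ax.set_ylabel("ROI")
    return ax
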