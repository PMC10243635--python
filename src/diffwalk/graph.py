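"""Undirected graph container, edge-list I/O and degree bookkeeping.

The walk model lives on a simple, unweighted, undirected graph: no
self-loops, no parallel edges, integer node ids compacted to ``0..N-1``.
Edges are stored canonically as an ``(m, 2)`` integer array with each row
sorted (``i < j``) and rows in lexicographic order, which makes equality,
hashing and serialisation deterministic.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger("diffwalk")

__all__ = [
    "UndirectedGraph",
    "TransitionMatrix",
    "read_edge_list",
    "write_edge_list",
    "read_coordinates",
    "write_coordinates",
    "largest_component",
    "transition_matrix",
    "thin_to_mean_degree",
]


def _canonicalize(pairs: np.ndarray) -> tuple[np.ndarray, int]:
    """Sort each pair, drop self-loops and duplicates; return (edges, n_loops)."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    loops = pairs[:, 0] == pairs[:, 1]
    n_loops = int(loops.sum())
    pairs = pairs[~loops]
    pairs = np.sort(pairs, axis=1)
    if len(pairs):
        pairs = np.unique(pairs, axis=0)
    else:
        pairs = pairs.reshape(0, 2)
    return pairs, n_loops


@dataclass(eq=False)
class UndirectedGraph:
    """Simple undirected graph with optional 3D node coordinates.

    Attributes
    ----------
    n_nodes : int
        Number of nodes; ids are ``0..n_nodes-1``.
    edges : ndarray of shape (m, 2)
        Canonical edge array (each row sorted, rows unique and sorted).
    coords : ndarray of shape (n_nodes, 3), optional
        Node positions in arbitrary length units.
    orig_ids : ndarray of shape (n_nodes,), optional
        Original input ids (``orig_ids[new] = old``) when the graph came
        from a file or a subgraph extraction.
    """

    n_nodes: int
    edges: np.ndarray
    coords: np.ndarray | None = None
    orig_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if len(self.edges):
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise ValueError("edge endpoint outside 0..n_nodes-1")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loop in canonical edge array")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        pairs,
        n_nodes: int | None = None,
        coords: np.ndarray | None = None,
    ) -> "UndirectedGraph":
        """Build a simple graph from an iterable of (i, j) pairs.

        Self-loops are dropped (with a logged warning) and duplicate /
        reversed-duplicate pairs collapse to a single edge.
        """
        pairs = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs)
        if pairs.size == 0:
            pairs = np.empty((0, 2), dtype=np.int64)
        edges, n_loops = _canonicalize(pairs)
        if n_loops:
            logger.warning("dropped %d self-loop(s) at graph construction", n_loops)
        if n_nodes is None:
            n_nodes = int(edges.max()) + 1 if len(edges) else 0
        return cls(n_nodes=n_nodes, edges=edges, coords=coords)

    # -- basic quantities --------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def degrees(self) -> np.ndarray:
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)

    @property
    def mean_degree(self) -> float:
        if self.n_nodes == 0:
            return 0.0
        return 2.0 * self.n_edges / self.n_nodes

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix in CSR format."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(self.edges))
        a = sp.coo_matrix(
            (data, (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_nodes, self.n_nodes),
        )
        return a.tocsr()

    def edge_hash(self) -> str:
        """SHA1 of the canonical edge array (graph identity for provenance)."""
        h = hashlib.sha1()
        h.update(np.int64(self.n_nodes).tobytes())
        h.update(np.ascontiguousarray(self.edges).tobytes())
        return h.hexdigest()

    # -- subgraphs ---------------------------------------------------------

    def subgraph(self, nodes: np.ndarray) -> "UndirectedGraph":
        """Induced subgraph on ``nodes``; ids recompacted preserving order."""
        nodes = np.asarray(nodes, dtype=np.int64)
        keep = np.zeros(self.n_nodes, dtype=bool)
        keep[nodes] = True
        new_id = -np.ones(self.n_nodes, dtype=np.int64)
        new_id[nodes] = np.arange(len(nodes))
        mask = keep[self.edges[:, 0]] & keep[self.edges[:, 1]]
        edges, _ = _canonicalize(new_id[self.edges[mask]])
        coords = self.coords[nodes] if self.coords is not None else None
        orig = self.orig_ids[nodes] if self.orig_ids is not None else nodes.copy()
        return UndirectedGraph(len(nodes), edges, coords=coords, orig_ids=orig)


@dataclass(eq=False)
class TransitionMatrix:
    """Row-stochastic one-step transition matrix T = D^-1 A of a walk.

    ``T[i, j] = 1/d_i`` iff ``{i, j}`` is an edge. The degree vector and the
    edge count (graph volume ``2E = sum d``) travel with the matrix because
    the stationary distribution ``pi = d / 2E`` is built from them.
    """

    T: sp.csr_matrix
    degrees: np.ndarray
    n_edges: int

    @property
    def n_nodes(self) -> int:
        return self.T.shape[0]


# ---------------------------------------------------------------------------
# I/O: whitespace-separated edge list, one edge per line, 0-based ids
# ---------------------------------------------------------------------------

def read_edge_list(path, coords_path=None) -> UndirectedGraph:
    """Read a whitespace-separated edge list into a simple graph.

    Node ids are compacted to ``0..N-1`` in order of first appearance; the
    original ids are kept in ``graph.orig_ids``. Duplicate lines (in either
    orientation) collapse to one edge and self-loops are dropped with a
    warning. Blank lines and ``#`` comments are ignored.

    Parameters
    ----------
    path : str or Path
        Edge-list file, two integer tokens per line.
    coords_path : str or Path, optional
        Companion CSV with header ``id,x,y,z`` giving 3D positions keyed
        by *original* node id.
    """
    raw = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two integer tokens, got {stripped!r}"
                )
            try:
                raw.append((int(tokens[0]), int(tokens[1])))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer token in {stripped!r}"
                ) from exc
    if not raw:
        raise ValueError(f"{path}: empty edge list")

    raw = np.asarray(raw, dtype=np.int64)
    flat = raw.ravel()
    uniq, first_pos = np.unique(flat, return_index=True)
    if uniq[0] == 0 and uniq[-1] == len(uniq) - 1:
        # ids already compact 0..N-1: keep them (round-trip identity)
        orig_ids = uniq
        compact = raw
    else:
        # compact in order of first appearance (row-major over tokens)
        order = np.argsort(first_pos)
        orig_ids = uniq[order]
        lookup = {old: new for new, old in enumerate(orig_ids)}
        compact = np.vectorize(lookup.__getitem__, otypes=[np.int64])(raw)

    edges, n_loops = _canonicalize(compact)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    g = UndirectedGraph(len(orig_ids), edges, orig_ids=orig_ids)
    if coords_path is not None:
        g.coords = read_coordinates(coords_path, orig_ids)
    return g


def write_edge_list(g: UndirectedGraph, path) -> None:
    """Write the canonical edge list (each edge once, tab-separated)."""
    with open(path, "w") as fh:
        for a, b in g.edges:
            fh.write(f"{a}\t{b}\n")


def read_coordinates(path, orig_ids: np.ndarray | None = None) -> np.ndarray:
    """Read an ``id,x,y,z`` CSV into an (N, 3) array aligned with node ids."""
    df = pd.read_csv(path)
    expected = ["id", "x", "y", "z"]
    if list(df.columns[:4]) != expected:
        raise ValueError(f"{path}: expected header id,x,y,z, got {list(df.columns)}")
    df = df.set_index("id")
    ids = orig_ids if orig_ids is not None else np.arange(len(df))
    missing = set(np.asarray(ids).tolist()) - set(df.index.tolist())
    if missing:
        raise ValueError(f"{path}: missing coordinates for {len(missing)} node(s)")
    return df.loc[np.asarray(ids), ["x", "y", "z"]].to_numpy(dtype=float)


def write_coordinates(g: UndirectedGraph, path) -> None:
    if g.coords is None:
        raise ValueError("graph has no coordinates")
    df = pd.DataFrame(g.coords, columns=["x", "y", "z"])
    df.insert(0, "id", np.arange(g.n_nodes))
    df.to_csv(path, index=False)


def write_id_map(g: UndirectedGraph, path) -> None:
    """Sidecar CSV mapping original input ids to compacted ids."""
    if g.orig_ids is None:
        raise ValueError("graph has no original-id map")
    df = pd.DataFrame({"old_id": g.orig_ids, "new_id": np.arange(g.n_nodes)})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Structure operations
# ---------------------------------------------------------------------------

def largest_component(g: UndirectedGraph) -> UndirectedGraph:
    """Induced subgraph on the largest connected component.

    Ties between equal-sized components are broken towards the component
    containing the smallest node id. Logs the fraction of nodes retained.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    n_comp, labels = connected_components(g.adjacency(), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best = sizes.max()
    # smallest node id whose component has maximal size
    winner = labels[np.flatnonzero(sizes[labels] == best)[0]]
    nodes = np.flatnonzero(labels == winner)
    sub = g.subgraph(nodes)
    frac = len(nodes) / g.n_nodes
    logger.info("largest_component: retained %d/%d nodes (%.1f%%)", len(nodes), g.n_nodes, 100 * frac)
    return sub


def transition_matrix(g: UndirectedGraph) -> TransitionMatrix:
    """Row-stochastic transition matrix T = D^-1 A of the simple walk."""
    d = g.degrees
    if np.any(d == 0):
        raise ValueError(
            "graph has isolated node(s); run largest_component first "
            f"(first isolated id: {int(np.flatnonzero(d == 0)[0])})"
        )
    a = g.adjacency()
    t = sp.diags(1.0 / d) @ a
    return TransitionMatrix(T=t.tocsr(), degrees=d, n_edges=g.n_edges)


def thin_to_mean_degree(g: UndirectedGraph, target: float, seed: int = 0) -> UndirectedGraph:
    """Remove uniformly random edges until mean degree first drops to <= target.

    Edges are removed one at a time in a seeded uniform-random order and the
    process stops at the first crossing below (or at) the target. Node count
    is unchanged; isolated nodes may appear (callers extract the largest
    component afterwards).
    """
    if target <= 0:
        raise ValueError("target mean degree must be positive")
    if target > g.mean_degree:
        raise ValueError(
            f"target mean degree {target} exceeds current {g.mean_degree:.6g}"
        )
    # first r with 2 (E - r) / N <= target
    r = math.ceil(g.n_edges - target * g.n_nodes / 2.0)
    r = max(r, 0)
    if r == 0:
        return UndirectedGraph(g.n_nodes, g.edges.copy(), coords=g.coords, orig_ids=g.orig_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(g.n_edges)
    kept, _ = _canonicalize(g.edges[perm[r:]])
    return UndirectedGraph(g.n_nodes, kept, coords=g.coords, orig_ids=g.orig_ids)
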