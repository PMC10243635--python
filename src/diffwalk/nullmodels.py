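"""Synthetic null-network generators for the heterogeneity workflow.

Four recipes, all seeded and parameterised so that desk-scale fixtures
and full-scale networks come from the same code:

* ``homogeneous_voronoi`` (HVor): Voronoi tessellation of a jittered cubic
  lattice clipped to a ball — a spatially homogeneous, quasi-regular 3D
  network. Default parameters build the full-scale variant (31^3 lattice,
  5185 retained seed points, thinned to mean degree 2.8), which matches
  the degree profile of the mouse lymph-node conduit network the workflow
  was designed around.
* ``polar_voronoi`` (PVor): Voronoi tessellation of two isotropic Gaussian
  seed clouds of very different density — a polarised network with a dense
  core off to one side.
* ``random_configuration``: stub-matching configuration model on a
  constant degree-3 sequence, simplified, then thinned — same degree
  profile, no spatial structure.
* ``rewire``: degree-preserving double-edge swaps applied to any graph,
  used to destroy spatial coherence progressively (2-20% of edges).

All generators thin to the target mean degree with the shared seeded
edge-removal routine, then return the largest connected component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import Voronoi, QhullError

from .graph import UndirectedGraph, largest_component, thin_to_mean_degree

__all__ = [
    "NullModelSpec",
    "homogeneous_voronoi",
    "polar_voronoi",
    "random_configuration",
    "rewire",
    "voronoi_graph",
]


def voronoi_graph(points: np.ndarray) -> UndirectedGraph:
    """Graph of the 3D Voronoi tessellation of a seed point cloud.

    Nodes are the finite Voronoi vertices; edges are the segments between
    consecutive vertices of each finite ridge polygon. Ridges touching the
    vertex at infinity are discarded entirely.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    try:
        vor = Voronoi(points)
    except QhullError as exc:
        raise ValueError(
            "degenerate Voronoi tessellation (co-spherical/coplanar seeds); "
            "add positional noise > 0"
        ) from exc
    pairs = []
    for ridge in vor.ridge_vertices:
        if -1 in ridge or len(ridge) < 2:
            continue
        for a, b in zip(ridge, ridge[1:] + ridge[:1]):
            if a != b:
                pairs.append((a, b) if a < b else (b, a))
    if not pairs:
        raise ValueError("tessellation produced no finite ridges; too few seeds")
    g = UndirectedGraph.from_edges(
        np.asarray(pairs, dtype=np.int64), n_nodes=len(vor.vertices)
    )
    g.coords = vor.vertices.copy()
    return g


def _finish(g: UndirectedGraph, target_mean_degree: float | None, seed: int) -> UndirectedGraph:
    if target_mean_degree is not None:
        g = thin_to_mean_degree(g, target_mean_degree, seed=seed)
    return largest_component(g)


def homogeneous_voronoi(
    grid_side: int = 31,
    noise: float = 0.2,
    sphere_keep: int = 5185,
    target_mean_degree: float | None = 2.8,
    seed: int = 0,
) -> UndirectedGraph:
    """Homogeneous Voronoi network (HVor).

    Builds an integer ``grid_side^3`` lattice centred at the origin, keeps
    the ``sphere_keep`` lattice points closest to the centre (rank-based
    ball clipping; ties broken lexicographically on coordinates), jitters
    every coordinate with seeded uniform noise in ``[-noise, noise]`` so
    the tessellation is generic (a perfect lattice would give degree-6
    Voronoi vertices instead of the generic degree 4), tessellates, thins
    to the target mean degree and returns the largest component.
    """
    if grid_side < 3:
        raise ValueError("grid_side must be >= 3")
    n_lattice = grid_side**3
    if sphere_keep > n_lattice:
        raise ValueError(f"sphere_keep {sphere_keep} exceeds lattice size {n_lattice}")
    axis = np.arange(grid_side, dtype=float) - (grid_side - 1) / 2.0
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    r2 = np.sum(pts**2, axis=1)
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], r2))
    pts = pts[order[:sphere_keep]]
    rng = np.random.default_rng(seed)
    if noise > 0:
        pts = pts + rng.uniform(-noise, noise, size=pts.shape)
    g = voronoi_graph(pts)
    return _finish(g, target_mean_degree, seed)


def polar_voronoi(
    n1: int = 10_000,
    center1=(0.0, 0.0, 0.0),
    sd1: float = 5.0,
    n2: int = 18_752,
    center2=(5.0, 5.0, 5.0),
    sd2: float = 1.0,
    target_mean_degree: float | None = 2.8,
    seed: int = 0,
) -> UndirectedGraph:
    """Polar Voronoi network (PVor) from two isotropic Gaussian seed clouds.

    The defaults place a broad cloud (sd 5, 10,000 seeds) at the origin and
    a much denser one (sd 1, 18,752 seeds) at (5,5,5), producing a strongly
    polarised node density. ``n2 = 0`` degenerates to a single-Gaussian
    isotropic Voronoi graph.
    """
    if n1 + n2 < 5:
        raise ValueError("need at least 5 seed points in total")
    rng = np.random.default_rng(seed)
    clouds = []
    if n1 > 0:
        clouds.append(rng.normal(loc=center1, scale=sd1, size=(n1, 3)))
    if n2 > 0:
        clouds.append(rng.normal(loc=center2, scale=sd2, size=(n2, 3)))
    pts = np.vstack(clouds)
    g = voronoi_graph(pts)
    return _finish(g, target_mean_degree, seed)


def random_configuration(
    n: int = 192_386,
    degree: int = 3,
    target_mean_degree: float | None = 2.8,
    seed: int = 0,
) -> UndirectedGraph:
    """Configuration-model network on a constant degree sequence.

    Stub matching on ``[degree] * n`` (n * degree must be even), then
    self-loops and parallel edges are removed, the result is thinned to the
    target mean degree and the largest component is returned.
    """
    if (n * degree) % 2 != 0:
        raise ValueError(f"degree sum n*degree = {n * degree} is odd; no such graph")
    gm = nx.configuration_model([degree] * n, seed=int(seed))
    simple = nx.Graph(gm)  # collapse parallel edges
    simple.remove_edges_from(nx.selfloop_edges(simple))
    edges = np.asarray(list(simple.edges), dtype=np.int64)
    g = UndirectedGraph.from_edges(edges, n_nodes=n)
    return _finish(g, target_mean_degree, seed)


def rewire(g: UndirectedGraph, fraction: float, seed: int = 0) -> UndirectedGraph:
    """Degree-preserving double-edge swaps touching ``fraction`` of the edges.

    Performs ``ceil(fraction * E / 2)`` successful swaps (each swap rewires
    two edges): edges (a,b),(c,d) become (a,d),(c,b), rejecting any swap
    that would create a self-loop or a duplicate edge. The degree sequence,
    node count and edge count are exactly preserved. Raises if 100x the
    requested number of attempts is exhausted.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if g.n_edges < 2:
        raise ValueError("need at least 2 edges to swap")
    n_swaps = math.ceil(fraction * g.n_edges / 2.0)
    out = UndirectedGraph(
        g.n_nodes, g.edges.copy(), coords=g.coords, orig_ids=g.orig_ids
    )
    if n_swaps == 0:
        return out
    rng = np.random.default_rng(seed)
    edges = out.edges.copy()
    edge_set = {tuple(e) for e in edges}
    done = 0
    attempts = 0
    max_attempts = 100 * n_swaps
    m = len(edges)
    while done < n_swaps:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"rewire: exhausted {max_attempts} attempts after {done}/{n_swaps} swaps"
            )
        attempts += 1
        e1, e2 = rng.choice(m, size=2, replace=False)
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.integers(2):  # random orientation of the second edge
            c, d = d, c
        # proposed: (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        old1 = tuple(int(x) for x in sorted((a, b)))
        old2 = tuple(int(x) for x in sorted((c, d)))
        if new1 in edge_set or new2 in edge_set or new1 == new2:
            continue
        edge_set.discard(old1)
        edge_set.discard(old2)
        edge_set.add(tuple(int(x) for x in new1))
        edge_set.add(tuple(int(x) for x in new2))
        edges[e1] = new1
        edges[e2] = new2
        done += 1
    canon = np.asarray(sorted(edge_set), dtype=np.int64)
    return UndirectedGraph(g.n_nodes, canon, coords=g.coords, orig_ids=g.orig_ids)


@dataclass
class NullModelSpec:
    """Parameters of one synthetic network recipe (config-file friendly).

    ``generator`` is one of ``hvor``, ``pvor``, ``random``; ``rewire_fraction``
    optionally applies degree-preserving rewiring to the generated graph.
    Unknown parameter keys are rejected by the underlying generator.
    """

    generator: str
    params: dict = field(default_factory=dict)
    rewire_fraction: float = 0.0
    seed: int = 0

    _BUILDERS = {
        "hvor": homogeneous_voronoi,
        "pvor": polar_voronoi,
        "random": random_configuration,
    }

    def build(self) -> UndirectedGraph:
        if self.generator not in self._BUILDERS:
            raise ValueError(
                f"unknown generator {self.generator!r}; choose from {sorted(self._BUILDERS)}"
            )
        if not 0.0 <= self.rewire_fraction <= 1.0:
            raise ValueError("rewire_fraction must be in [0, 1]")
        g = self._BUILDERS[self.generator](seed=self.seed, **self.params)
        if self.rewire_fraction > 0:
            g = rewire(g, self.rewire_fraction, seed=self.seed + 1)
        return g
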