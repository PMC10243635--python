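"""Diffusion-community detection: k-means in diffusion-coordinate space.

Communities are clusters of the node point-cloud embedded at a reference
walk time, by default the relaxation time ``tau = 1/(1-|lambda_1|)``.
Nodes of one community launch walkers with correlated presence fields;
the downstream features (Cheeger mixing index, entry/exit probabilities)
are all computed per community.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .spectral import DiffusionMap

__all__ = ["DiffusionCommunities", "CommunityPartition", "detect_communities", "community_sizes"]


@dataclass(eq=False)
class CommunityPartition:
    """Assignment of every node to one of k diffusion communities."""

    labels: np.ndarray
    k: int
    t_embed: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        sizes = np.bincount(self.labels, minlength=self.k)
        if len(sizes) > self.k:
            raise ValueError("label outside 0..k-1")
        if np.any(sizes == 0):
            raise ValueError("empty community in partition")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


class DiffusionCommunities(ClusterMixin, BaseEstimator):
    """k-means clustering of nodes in diffusion-coordinate space.

    The embedding is ``X_K(t)`` with the constant first column dropped
    (it carries no information). ``t`` defaults to ``floor(tau)``; at that
    time most coordinates have decayed to zero and clustering acts on the
    surviving slow modes, which is exactly the long-time structure the
    communities are meant to capture.

    Parameters
    ----------
    n_clusters : int, default=100
        Number of communities k.
    n_components : int, default=2000
        Truncation order K of the embedding when fitting from a graph.
    t : int or "relaxation", default="relaxation"
        Embedding time.
    random_state : int, default=0
        Seeds both the eigensolver start vector and k-means++.
    n_init, tol : k-means restarts (default 10) and relative inertia
        tolerance (default 1e-6).

    Attributes
    ----------
    labels_ : ndarray of shape (N,) — community id per node.
    t_embed_ : int — embedding time actually used.
    embedding_ : fitted :class:`DiffusionMap`.
    """

    def __init__(
        self,
        n_clusters: int = 100,
        n_components: int = 2000,
        t="relaxation",
        random_state: int = 0,
        n_init: int = 10,
        tol: float = 1e-6,
    ):
        self.n_clusters = n_clusters
        self.n_components = n_components
        self.t = t
        self.random_state = random_state
        self.n_init = n_init
        self.tol = tol

    def fit(self, X, y=None) -> "DiffusionCommunities":
        """Cluster nodes of X (graph, adjacency, or fitted DiffusionMap)."""
        if isinstance(X, DiffusionMap):
            model = X
            model._check_fitted()
        else:
            from .spectral import _as_transition

            tm = _as_transition(X)
            model = DiffusionMap(
                n_components=min(self.n_components, tm.n_nodes),
                random_state=self.random_state,
            ).fit(tm)
        n = model.n_nodes_
        k = int(self.n_clusters)
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters must be in 1..{n}, got {k}")
        t = model._resolve_time(self.t)
        coords = model.coordinates(t)[:, 1:]  # drop the constant column

        if k == n:
            labels = np.arange(n)
        else:
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=self.n_init,
                tol=self.tol,
                random_state=self.random_state,
            )
            labels = km.fit_predict(coords)
            labels = _repair_empty(labels, coords, k)

        self.labels_ = labels
        self.t_embed_ = t
        self.embedding_ = model
        return self

    def to_partition(self) -> CommunityPartition:
        return CommunityPartition(
            labels=self.labels_,
            k=int(self.n_clusters),
            t_embed=self.t_embed_,
            seed=self.random_state,
        )


def _repair_empty(labels: np.ndarray, coords: np.ndarray, k: int) -> np.ndarray:
    """Re-seed any empty cluster from the point farthest from its centroid.

    sklearn's Lloyd iterations already relocate empty clusters, so this only
    triggers in degenerate cases (e.g. fewer distinct embedding points than
    clusters after heavy eigenvalue underflow).
    """
    labels = labels.copy()
    for cid in range(k):
        while (sizes := np.bincount(labels, minlength=k))[cid] == 0:
            donor = int(np.argmax(sizes))
            if sizes[donor] <= 1:
                raise ValueError("cannot repair empty community: not enough points")
            members = np.flatnonzero(labels == donor)
            centroid = coords[members].mean(axis=0)
            far = members[np.argmax(np.linalg.norm(coords[members] - centroid, axis=1))]
            labels[far] = cid
    return labels


def detect_communities(
    model: DiffusionMap, k: int, t=None, seed: int = 0
) -> CommunityPartition:
    """k diffusion communities of a fitted model at time t (default floor(tau))."""
    est = DiffusionCommunities(
        n_clusters=k,
        t="relaxation" if t is None else t,
        random_state=seed,
    )
    est.fit(model)
    return est.to_partition()


def community_sizes(p: CommunityPartition) -> np.ndarray:
    """Node count per community (sums to N)."""
    return p.sizes()
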