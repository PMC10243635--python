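"""Truncated biorthogonal spectral decomposition of the random-walk operator.

The transition matrix ``T = D^-1 A`` of a simple walk on a connected graph
is conjugate to the symmetric matrix ``M = D^-1/2 A D^-1/2``, so its
eigensystem can be obtained from a symmetric (sparse) eigensolver. With
``M v_k = lambda_k v_k`` and orthonormal ``v_k``, the right and left
eigenvectors of T are

    psi_k = sqrt(2E) D^-1/2 v_k      (T psi_k = lambda_k psi_k)
    phi_k = D^1/2 v_k / sqrt(2E)     (phi_k^T T = lambda_k phi_k^T)

normalised so that ``Phi^T Psi = I``, ``psi_0 = 1`` and
``phi_0 = d / 2E`` (the stationary distribution). Keeping only the K
largest-magnitude eigenpairs gives the truncated operator
``T_K^t = Psi_K Lambda_K^t Phi_K^T`` used for diffusion coordinates,
presence fields and community-level entry/exit probabilities at any
integer time t without ever forming a dense power of T.
"""

from __future__ import annotations

import numbers

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .graph import TransitionMatrix, UndirectedGraph, transition_matrix

__all__ = [
    "DiffusionMap",
    "RelaxationUndefinedError",
    "spectral_decomposition",
    "diffusion_coordinates",
    "diffusion_distance",
    "presence_field",
    "relaxation_time",
    "truncation_error",
    "eigenvalue_power",
]

#: |lambda_1| at or above this is treated as a second unit-magnitude mode
#: (bipartite or disconnected graph) and the relaxation time is undefined.
UNIT_EIGENVALUE_TOL = 1e-9


class RelaxationUndefinedError(ValueError):
    """Raised when tau = 1/(1 - |lambda_1|) does not exist (|lambda_1| = 1)."""


def eigenvalue_power(lambdas: np.ndarray, t: int) -> np.ndarray:
    """Sign-aware ``lambda**t`` in log space, underflowing gracefully to 0.

    For the huge walk times this workflow needs (relaxation times of order
    1e4 and beyond) a naive power would overflow the exponent range of the
    intermediate computation for negative bases; instead use
    ``sign(lambda)^t * exp(t * log|lambda|)``.
    """
    if t < 0:
        raise ValueError("time must be a nonnegative integer")
    lambdas = np.asarray(lambdas, dtype=float)
    if t == 0:
        return np.ones_like(lambdas)
    out = np.zeros_like(lambdas)
    mag = np.abs(lambdas)
    nz = mag > 0.0
    with np.errstate(under="ignore"):
        powed = np.exp(t * np.log(mag[nz]))
    if t % 2 == 1:
        powed = np.where(lambdas[nz] < 0, -powed, powed)
    out[nz] = powed
    return out


def _as_transition(X) -> TransitionMatrix:
    if isinstance(X, TransitionMatrix):
        return X
    if isinstance(X, UndirectedGraph):
        return transition_matrix(X)
    a = sp.csr_matrix(X)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    d = np.asarray(a.sum(axis=1)).ravel()
    if np.any(d == 0):
        raise ValueError("adjacency has zero-degree rows; extract the largest component")
    t = sp.diags(1.0 / d) @ a
    return TransitionMatrix(T=t.tocsr(), degrees=d, n_edges=int(round(d.sum() / 2)))


class DiffusionMap(BaseEstimator):
    """Truncated diffusion-map embedding of a random walk on a graph.

    Fitting computes the ``n_components`` largest-magnitude eigenpairs of
    the symmetrised walk operator and stores the biorthogonal system
    (``eigenvalues_``, ``psi_``, ``phi_``). The embedding at integer time t
    is ``X_K(t) = Psi_K Lambda_K^t`` whose rows are the diffusion
    coordinates of the nodes; Euclidean distances between rows (ignoring
    the constant first column) are diffusion distances.

    Parameters
    ----------
    n_components : int, default=2000
        Truncation order K (number of retained eigenpairs, largest
        magnitude first; the stationary pair is always index 0).
    t : int or "relaxation", default="relaxation"
        Embedding time used by :meth:`fit_transform`; "relaxation" means
        ``floor(tau)`` with ``tau = 1/(1 - |lambda_1|)``.
    random_state : int or RandomState, default=0
        Seeds the Lanczos start vector so repeated fits agree to the sign
        convention.
    dense_cutoff : int, default=2000
        Below this many nodes (or when K is within 2 of N) the dense
        symmetric solver is used instead of Lanczos iteration.

    Attributes
    ----------
    eigenvalues_ : ndarray of shape (K,)
        Eigenvalues of T sorted by decreasing magnitude, ``lambda_0 = 1``.
    psi_ : ndarray of shape (N, K)
        Right eigenvectors; ``psi_[:, 0] == 1``.
    phi_ : ndarray of shape (N, K)
        Left eigenvectors; ``phi_[:, 0] == d/2E``; ``phi_.T @ psi_ == I``.
    degrees_, n_edges_, n_nodes_ : degree vector and graph volume metadata.
    graph_hash_ : SHA1 of the canonical edge set when fitted from a graph.
    """

    def __init__(
        self,
        n_components: int = 2000,
        t="relaxation",
        random_state=0,
        dense_cutoff: int = 2000,
    ):
        self.n_components = n_components
        self.t = t
        self.random_state = random_state
        self.dense_cutoff = dense_cutoff

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None) -> "DiffusionMap":
        """Compute the truncated eigensystem of the walk on X.

        X may be an :class:`UndirectedGraph`, a :class:`TransitionMatrix`
        or a symmetric (sparse) adjacency matrix.
        """
        tm = _as_transition(X)
        n = tm.n_nodes
        k = int(self.n_components)
        if not 1 <= k <= n:
            raise ValueError(f"n_components must be in 1..{n}, got {k}")
        d = tm.degrees.astype(float)
        two_e = float(d.sum())
        dm12 = 1.0 / np.sqrt(d)
        a = tm.T.multiply(d[:, None])  # recover A = D T
        m = sp.diags(dm12) @ a @ sp.diags(dm12)

        if n <= self.dense_cutoff or k >= n - 1:
            w, v = scipy.linalg.eigh(np.asarray(m.todense()))
        else:
            rng = check_random_state(self.random_state)
            v0 = rng.uniform(-1.0, 1.0, size=n)
            w, v = spla.eigsh(m.tocsr(), k=k, which="LM", v0=v0)

        # order by decreasing |lambda|, positive first on magnitude ties
        order = np.lexsort((-w, -np.abs(w)))[:k]
        w = np.clip(w[order], -1.0, 1.0)
        v = v[:, order]
        # sign convention: largest-magnitude entry of each v_k positive
        pivot = np.argmax(np.abs(v), axis=0)
        v *= np.sign(v[pivot, np.arange(k)])

        psi = np.sqrt(two_e) * dm12[:, None] * v
        phi = np.sqrt(d)[:, None] * v / np.sqrt(two_e)
        # the stationary pair is known in closed form; pin it exactly
        if not np.isclose(w[0], 1.0, atol=1e-6):
            raise ValueError(
                f"leading eigenvalue {w[0]:.6f} != 1; is the graph connected?"
            )
        w[0] = 1.0
        psi[:, 0] = 1.0
        phi[:, 0] = d / two_e

        self.eigenvalues_ = w
        self.psi_ = psi
        self.phi_ = phi
        self.degrees_ = tm.degrees
        self.n_edges_ = tm.n_edges
        self.n_nodes_ = n
        self.graph_hash_ = X.edge_hash() if isinstance(X, UndirectedGraph) else None
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return diffusion coordinates at the configured time."""
        self.fit(X)
        return self.coordinates(self._resolve_time(self.t))

    # -- derived quantities ------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "eigenvalues_"):
            raise AttributeError("DiffusionMap is not fitted yet; call fit first")

    def _resolve_time(self, t) -> int:
        if t == "relaxation":
            return int(np.floor(self.relaxation_time()))
        if not isinstance(t, numbers.Integral) or t < 0:
            raise ValueError(f"time must be a nonnegative integer, got {t!r}")
        return int(t)

    def coordinates(self, t: int) -> np.ndarray:
        """Diffusion coordinates ``X_K(t) = Psi_K Lambda_K^t`` (N x K)."""
        self._check_fitted()
        t = self._resolve_time(t)
        return self.psi_ * eigenvalue_power(self.eigenvalues_, t)

    def presence_field(self, i: int, t: int) -> np.ndarray:
        """Probability field ``p(j, t | i)`` through the truncated spectrum.

        At full rank (K = N) the result is row i of ``T^t`` and sums to 1;
        for K < N the sum reports the retained probability mass.
        """
        self._check_fitted()
        t = self._resolve_time(t)
        lam_t = eigenvalue_power(self.eigenvalues_, t)
        return self.phi_ @ (lam_t * self.psi_[i])

    def diffusion_distance(self, i0: int, i1: int, t: int) -> float:
        """Diffusion distance ``D_t(i0, i1)`` between two nodes at time t.

        ``D_t^2 = sum_{k>=1} lambda_k^{2t} (psi_k(i0) - psi_k(i1))^2``; at
        full rank this equals the degree-weighted l2 distance between the
        two presence fields.
        """
        self._check_fitted()
        t = self._resolve_time(t)
        lam_2t = eigenvalue_power(self.eigenvalues_[1:], t) ** 2
        diff = self.psi_[i0, 1:] - self.psi_[i1, 1:]
        return float(np.sqrt(np.sum(lam_2t * diff**2)))

    def relaxation_time(self) -> float:
        """Relaxation time ``tau = 1 / (1 - |lambda_1|)`` of the walk."""
        self._check_fitted()
        if len(self.eigenvalues_) < 2:
            raise ValueError("need at least 2 eigenpairs to compute tau")
        lam1 = self.eigenvalues_[1]
        if abs(lam1) >= 1.0 - UNIT_EIGENVALUE_TOL:
            cause = "bipartite graph (eigenvalue -1)" if lam1 < 0 else (
                "disconnected graph (repeated eigenvalue 1)"
            )
            raise RelaxationUndefinedError(
                f"relaxation time undefined: |lambda_1| = {abs(lam1):.12f} ~ 1; {cause}"
            )
        return 1.0 / (1.0 - abs(lam1))

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Serialise the fitted eigensystem to a single ``.npz`` container."""
        self._check_fitted()
        np.savez_compressed(
            path,
            eigenvalues=self.eigenvalues_,
            psi=self.psi_,
            phi=self.phi_,
            degrees=self.degrees_,
            n_edges=self.n_edges_,
            graph_hash=self.graph_hash_ or "",
            n_components=self.n_components,
        )

    @classmethod
    def load(cls, path) -> "DiffusionMap":
        data = np.load(path, allow_pickle=False)
        model = cls(n_components=int(data["n_components"]))
        model.eigenvalues_ = data["eigenvalues"]
        model.psi_ = data["psi"]
        model.phi_ = data["phi"]
        model.degrees_ = data["degrees"]
        model.n_edges_ = int(data["n_edges"])
        model.n_nodes_ = model.psi_.shape[0]
        gh = str(data["graph_hash"])
        model.graph_hash_ = gh or None
        return model


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def spectral_decomposition(X, K: int, random_state=0) -> DiffusionMap:
    """Fit a :class:`DiffusionMap` with truncation order K on X."""
    return DiffusionMap(n_components=K, random_state=random_state).fit(X)


def diffusion_coordinates(model: DiffusionMap, t: int) -> np.ndarray:
    return model.coordinates(t)


def diffusion_distance(model: DiffusionMap, i0: int, i1: int, t: int) -> float:
    return model.diffusion_distance(i0, i1, t)


def presence_field(model: DiffusionMap, i: int, t: int) -> tuple[np.ndarray, float]:
    """Presence field and its retained (truncated) probability mass."""
    p = model.presence_field(i, t)
    return p, float(p.sum())


def relaxation_time(model: DiffusionMap) -> float:
    return model.relaxation_time()


def truncation_error(
    tm: TransitionMatrix | UndirectedGraph,
    K: int,
    t: int,
    cap: int = 2000,
    random_state=0,
) -> float:
    """Relative spectral-norm error of the rank-K operator at time t.

    Computes ``||T^t - T_K^t||_2 / ||T^t||_2`` against an exact dense power
    of T, so it is only available for graphs small enough for dense linear
    algebra (``N <= cap``).
    """
    tm = _as_transition(tm) if not isinstance(tm, TransitionMatrix) else tm
    n = tm.n_nodes
    if n > cap:
        raise ValueError(
            f"truncation_error needs dense T^t; N={n} exceeds cap={cap} — use a smaller fixture"
        )
    if t < 0 or int(t) != t:
        raise ValueError("time must be a nonnegative integer")
    model = DiffusionMap(n_components=K, random_state=random_state).fit(tm)
    t_dense = tm.T.toarray()
    t_exact = np.linalg.matrix_power(t_dense, int(t))
    lam_t = eigenvalue_power(model.eigenvalues_, int(t))
    t_hat = (model.psi_ * lam_t) @ model.phi_.T
    return float(np.linalg.norm(t_exact - t_hat, 2) / np.linalg.norm(t_exact, 2))
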