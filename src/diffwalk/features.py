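"""Per-community descriptors of the walk: mixing, entry/exit, heterogeneity.

Two families of features are computed for each diffusion community C:

* the **Cheeger mixing index** ``h(C) = cut(C, C_bar) / min(vol C, vol C_bar)``,
  a static conductance-style measure of how compact the community is in
  the graph (low h means diffusion-close nodes are also path-close,
  i.e. high spatial coherence);

* the **mean entry and exit probabilities** ``<p_in>_C(t)`` and
  ``<p_out>_C(t)`` — the per-pair probability that a walker started
  outside C sits inside it after t steps (and vice versa) — evaluated
  through the truncated spectrum with per-community eigenvector sums, so
  the cost is O(K N) per time rather than a dense matrix power.

The across-community standard deviation of the entry/exit features,
maximised over a time grid, is the heterogeneity statistic used to
compare networks; the minimum of per-community entry/exit values at the
biological scan time locates "remote" regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import CommunityPartition
from .graph import UndirectedGraph
from .spectral import DiffusionMap, eigenvalue_power

__all__ = [
    "TimeGrid",
    "make_time_grid",
    "cheeger_index",
    "mean_cheeger",
    "entry_probability",
    "exit_probability",
    "entry_exit_profiles",
    "HeterogeneityResult",
    "heterogeneity",
    "rank_communities",
    "scan_steps",
    "community_features",
]


# ---------------------------------------------------------------------------
# Time grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing positive integer walk times; one entry is floor(tau)."""

    steps: tuple
    tau_index: int

    def __post_init__(self):
        steps = tuple(int(s) for s in self.steps)
        if not steps:
            raise ValueError("empty time grid")
        if any(s <= 0 for s in steps):
            raise ValueError("time grid steps must be positive")
        if list(steps) != sorted(set(steps)):
            raise ValueError("time grid steps must be strictly increasing")
        object.__setattr__(self, "steps", steps)
        if not 0 <= self.tau_index < len(steps):
            raise ValueError("tau_index out of range")

    def __iter__(self):
        return iter(self.steps)

    def __len__(self):
        return len(self.steps)


def make_time_grid(tau: float, n_points: int = 12, horizon: float = 2.0) -> TimeGrid:
    """~n_points log-spaced integer times from 1 to horizon*floor(tau).

    floor(tau) is always included and flagged; duplicates from integer
    rounding are collapsed.
    """
    t_tau = max(int(math.floor(tau)), 1)
    t_max = max(int(round(horizon * t_tau)), t_tau)
    raw = np.unique(
        np.round(np.logspace(0, np.log10(t_max), n_points)).astype(int)
    )
    steps = sorted(set(raw.tolist()) | {t_tau})
    return TimeGrid(steps=tuple(steps), tau_index=steps.index(t_tau))


# ---------------------------------------------------------------------------
# Cheeger mixing index
# ---------------------------------------------------------------------------

def cheeger_index(g: UndirectedGraph, p: CommunityPartition, c: int) -> float:
    """Cut edges between community c and its complement over the smaller volume."""
    in_c = p.labels == c
    n_c = int(in_c.sum())
    if n_c == 0:
        raise ValueError(f"community {c} is empty")
    if n_c == g.n_nodes:
        raise ValueError(f"community {c} is the whole node set; h undefined")
    e0 = in_c[g.edges[:, 0]]
    e1 = in_c[g.edges[:, 1]]
    cut = int(np.sum(e0 != e1))
    d = g.degrees
    vol_c = int(d[in_c].sum())
    vol_rest = int(d[~in_c].sum())
    return cut / min(vol_c, vol_rest)


def mean_cheeger(g: UndirectedGraph, p: CommunityPartition) -> float:
    """Unweighted mean of h(C) over all k communities (k >= 2)."""
    if p.k < 2:
        raise ValueError("mean Cheeger index needs at least 2 communities")
    return float(np.mean([cheeger_index(g, p, c) for c in range(p.k)]))


# ---------------------------------------------------------------------------
# Mean entry / exit probabilities
# ---------------------------------------------------------------------------

def _community_sums(model: DiffusionMap, labels: np.ndarray, k: int):
    """Per-community column sums of psi and phi: (k, K) arrays."""
    n, K = model.psi_.shape
    s_psi = np.zeros((k, K))
    s_phi = np.zeros((k, K))
    np.add.at(s_psi, labels, model.psi_)
    np.add.at(s_phi, labels, model.phi_)
    return s_psi, s_phi


def entry_exit_profiles(
    model: DiffusionMap, p: CommunityPartition, times
) -> tuple[np.ndarray, np.ndarray]:
    """``<p_in>_C(t)`` and ``<p_out>_C(t)`` for every community and time.

    Returns two (k, n_times) arrays. Uses community-summed eigenvector
    components: with ``S_psi(C) = sum_{m in C} psi_k(m)`` and
    ``S_phi(C) = sum_{l in C} phi_k(l)``,

        <p_in>_C(t)  = sum_k S_psi(C_bar, k) lambda_k^t S_phi(C, k) / (n_C n_Cbar)
        <p_out>_C(t) = sum_k S_psi(C, k) lambda_k^t S_phi(C_bar, k) / (n_C n_Cbar)
    """
    times = [int(t) for t in times]
    labels = p.labels
    k = p.k
    sizes = np.bincount(labels, minlength=k).astype(float)
    if np.any(sizes == 0):
        raise ValueError("empty community")
    if np.any(sizes == p.n_nodes):
        raise ValueError("a community covers the whole graph; complement empty")
    s_psi, s_phi = _community_sums(model, labels, k)
    tot_psi = s_psi.sum(axis=0)
    tot_phi = s_phi.sum(axis=0)
    out_psi = tot_psi[None, :] - s_psi  # sums over the complement
    out_phi = tot_phi[None, :] - s_phi
    denom = sizes * (p.n_nodes - sizes)

    p_in = np.empty((k, len(times)))
    p_out = np.empty((k, len(times)))
    for j, t in enumerate(times):
        lam_t = eigenvalue_power(model.eigenvalues_, t)
        p_in[:, j] = np.sum(out_psi * lam_t[None, :] * s_phi, axis=1) / denom
        p_out[:, j] = np.sum(s_psi * lam_t[None, :] * out_phi, axis=1) / denom
    return p_in, p_out


def entry_probability(
    model: DiffusionMap, p: CommunityPartition, c: int, t: int
) -> float:
    """Mean probability over (source outside C, target in C) pairs at time t."""
    p_in, _ = entry_exit_profiles(model, p, [t])
    return float(p_in[c, 0])


def exit_probability(
    model: DiffusionMap, p: CommunityPartition, c: int, t: int
) -> float:
    """Mean probability over (source in C, target outside C) pairs at time t."""
    _, p_out = entry_exit_profiles(model, p, [t])
    return float(p_out[c, 0])


# ---------------------------------------------------------------------------
# Heterogeneity statistic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeterogeneityResult:
    """SD across communities of <p_in>/<p_out> per time, and the time maxima."""

    times: tuple
    sd_pin: np.ndarray
    sd_pout: np.ndarray
    max_sd_pin: float
    max_sd_pout: float


def heterogeneity(
    model: DiffusionMap, p: CommunityPartition, grid: TimeGrid
) -> HeterogeneityResult:
    """max over the grid of the across-community SD of entry/exit probabilities.

    The SD is the population standard deviation over the k community values
    (ddof=0); higher maxima mean a more heterogeneous network.
    """
    if p.k < 2:
        raise ValueError("heterogeneity needs at least 2 communities")
    p_in, p_out = entry_exit_profiles(model, p, grid.steps)
    sd_pin = p_in.std(axis=0, ddof=0)
    sd_pout = p_out.std(axis=0, ddof=0)
    return HeterogeneityResult(
        times=tuple(grid.steps),
        sd_pin=sd_pin,
        sd_pout=sd_pout,
        max_sd_pin=float(sd_pin.max()),
        max_sd_pout=float(sd_pout.max()),
    )


def rank_communities(
    values, m: int, direction: str = "lowest", as_percentage: bool = False
):
    """Ids of the m extreme communities sorted by value.

    direction="lowest" returns the m smallest (ascending); "highest" the m
    largest (descending). With ``as_percentage`` the values are also
    returned as a percentage of the mean across all communities.
    """
    values = np.asarray(values, dtype=float)
    if m > len(values):
        raise ValueError("m exceeds the number of communities")
    if direction not in ("lowest", "highest"):
        raise ValueError("direction must be 'lowest' or 'highest'")
    order = np.argsort(values, kind="stable")
    ids = order[:m] if direction == "lowest" else order[::-1][:m]
    if as_percentage:
        return ids, 100.0 * values[ids] / values.mean()
    return ids


# ---------------------------------------------------------------------------
# Biological step-time conversion
# ---------------------------------------------------------------------------

def scan_steps(residence: float, speed: float, edge_length: float) -> int:
    """Number of walk steps in a residence time.

    The per-step duration is ``edge_length / speed`` rounded to two decimal
    places (minutes); the step count is ``floor(residence / per_step)``.
    With the default T-cell figures — 12 h residence, 13 um/min speed,
    10 um edges — one step is 0.77 min and a 12 h scan is 935 steps.
    """
    if residence <= 0 or speed <= 0 or edge_length <= 0:
        raise ValueError("residence, speed and edge_length must all be positive")
    per_step = round(edge_length / speed, 2)
    if per_step <= 0:
        raise ValueError("per-step time rounds to zero; check units")
    return int(math.floor(residence / per_step))


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

def community_features(
    g: UndirectedGraph,
    model: DiffusionMap,
    p: CommunityPartition,
    grid: TimeGrid,
) -> pd.DataFrame:
    """Per-community table: size, mean degree, Cheeger index, p_in/p_out on the grid."""
    sizes = p.sizes()
    d = g.degrees
    mean_deg = np.array([d[p.labels == c].mean() for c in range(p.k)])
    cheeger = np.array([cheeger_index(g, p, c) for c in range(p.k)])
    p_in, p_out = entry_exit_profiles(model, p, grid.steps)
    df = pd.DataFrame(
        {
            "community_id": np.arange(p.k),
            "n_c": sizes,
            "mean_degree": mean_deg,
            "cheeger": cheeger,
        }
    )
    for j, t in enumerate(grid.steps):
        df[f"p_in@{t}"] = p_in[:, j]
    for j, t in enumerate(grid.steps):
        df[f"p_out@{t}"] = p_out[:, j]
    return df
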