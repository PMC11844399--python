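"""Analytic communication metrics on a connectome.

The walk model: a signal at region ``i`` hops to region ``k`` with
probability ``M_ik = A_ik / D_ii`` — the fraction of tracts at ``i`` that
lead to ``k``.  The hitting time ``H_ij`` is the expected number of hops
from ``i`` to ``j``; the commute time ``C_ij = H_ij + H_ji`` is the
round-trip expectation and is symmetric.  Both have closed forms in the
Laplacian pseudoinverse ``Γ⁺``:

    H_ij = Σ_k (Γ⁺_ik − Γ⁺_ji − Γ⁺_jk + Γ⁺_jj) D_kk
    C_ij = (Γ⁺_ii + Γ⁺_jj − 2 Γ⁺_ij) Σ_k D_kk

Comparator metrics: commute time via the Markov-chain fundamental matrix
(mean first passage times), communicability (matrix exponential of the
degree-normalized adjacency), and search information (bits a random walker
needs to follow the shortest path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, solve
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .graph_core import (
    Connectome,
    DegreeDiagonal,
    DisconnectedGraphError,
    LaplacianOperator,
    degree_diagonal,
    laplacian,
)

METRIC_NAMES = (
    "commute_time",
    "mfpt_commute",
    "communicability",
    "search_information_sym",
    "structural_connectivity",
    "fc",
)


@dataclass(frozen=True)
class HittingTimeMatrix:
    """Asymmetric region × region expected step counts; zero diagonal."""

    values: np.ndarray
    labels: tuple


@dataclass(frozen=True)
class PairwiseMatrix:
    """Symmetric region × region matrix tagged with the metric it holds."""

    values: np.ndarray
    metric_name: str
    labels: tuple
    diagonal_policy: str = "zero"
    meta: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def offdiag_values(self, pairs: np.ndarray | None = None) -> np.ndarray:
        """Vectorize over unordered off-diagonal pairs (or a supplied pair list)."""
        if pairs is None:
            iu = np.triu_indices(self.n_regions, k=1)
            return self.values[iu]
        pairs = np.asarray(pairs)
        return self.values[pairs[:, 0], pairs[:, 1]]


def transition_matrix(c: Connectome) -> np.ndarray:
    """First-order Markov transition matrix ``M = D⁻¹ A``."""
    deg = degree_diagonal(c)
    return c.weights / deg.values[:, None]


def hitting_time_matrix(lap: LaplacianOperator, deg: DegreeDiagonal,
                        labels=None) -> HittingTimeMatrix:
    """Expected steps ``H_ij`` from every source i to target j (closed form)."""
    g = lap.pseudoinverse
    d = deg.values
    vol = deg.volume
    gd = g @ d  # (Γ⁺ D 1)_i
    # H_ij = (Γ⁺ d)_i − (Γ⁺ d)_j + vol (Γ⁺_jj − Γ⁺_ij), using Γ⁺ symmetry
    h = gd[:, None] - gd[None, :] + vol * (np.diag(g)[None, :] - g)
    np.fill_diagonal(h, 0.0)
    n = h.shape[0]
    if labels is None:
        labels = tuple(f"region_{i:03d}" for i in range(n))
    return HittingTimeMatrix(values=h, labels=tuple(labels))


def commute_time_matrix(lap: LaplacianOperator, deg: DegreeDiagonal,
                        labels=None) -> PairwiseMatrix:
    """Round-trip expectation ``C_ij = (Γ⁺_ii + Γ⁺_jj − 2Γ⁺_ij) Σ_k D_kk``."""
    g = lap.pseudoinverse
    dg = np.diag(g)
    c = (dg[:, None] + dg[None, :] - 2.0 * g) * deg.volume
    np.fill_diagonal(c, 0.0)
    n = c.shape[0]
    if labels is None:
        labels = tuple(f"region_{i:03d}" for i in range(n))
    return PairwiseMatrix(values=c, metric_name="commute_time",
                          labels=tuple(labels), diagonal_policy="zero")


def commute_time(c: Connectome, zero_tolerance: float = 1e-10) -> PairwiseMatrix:
    """Convenience: commute-time matrix straight from a connectome."""
    return commute_time_matrix(laplacian(c, zero_tolerance), degree_diagonal(c),
                               labels=c.labels)


def hitting_time(c: Connectome, zero_tolerance: float = 1e-10) -> HittingTimeMatrix:
    """Convenience: hitting-time matrix straight from a connectome."""
    return hitting_time_matrix(laplacian(c, zero_tolerance), degree_diagonal(c),
                               labels=c.labels)


def mfpt_commute_matrix(c: Connectome) -> PairwiseMatrix:
    """Commute time via mean first passage times of the stationary chain.

    Builds the fundamental matrix ``Z = (I − M + 1πᵀ)⁻¹`` with stationary
    distribution ``π_i = D_ii / Σ_k D_kk`` and mean first passage time
    ``MFPT_ij = (Z_jj − Z_ij) / π_j``; returns the symmetrized sum
    ``MFPT + MFPTᵀ``.  An independent route to the same physics as the
    pseudoinverse formula.
    """
    deg = degree_diagonal(c)
    m = transition_matrix(c)
    n = c.n_regions
    pi = deg.values / deg.volume
    try:
        z = solve(np.eye(n) - m + np.outer(np.ones(n), pi), np.eye(n))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - connected graphs
        raise DisconnectedGraphError(
            "fundamental matrix system is singular (graph disconnected?)") from exc
    mfpt = (np.diag(z)[None, :] - z) / pi[None, :]
    np.fill_diagonal(mfpt, 0.0)
    sym = mfpt + mfpt.T
    return PairwiseMatrix(values=sym, metric_name="mfpt_commute",
                          labels=c.labels, diagonal_policy="zero")


def communicability_matrix(c: Connectome, normalized: bool = True) -> PairwiseMatrix:
    """Communicability ``exp(D^{-1/2} A D^{-1/2})``.

    Weights every walk of length n between two regions by 1/n!, after
    normalizing the adjacency by node strengths so that uniform rescaling
    of tract counts cancels.  ``normalized=False`` gives the raw ``exp(A)``
    for sensitivity checks.  The diagonal is a well-defined self-walk term
    and is kept (``diagonal_policy='defined'``) but excluded from pair
    correlations downstream.
    """
    if normalized:
        deg = degree_diagonal(c)
        inv_sqrt = 1.0 / np.sqrt(deg.values)
        a = c.weights * inv_sqrt[:, None] * inv_sqrt[None, :]
    else:
        a = c.weights
    cmy = expm(a)
    cmy = (cmy + cmy.T) / 2.0
    return PairwiseMatrix(values=cmy, metric_name="communicability",
                          labels=c.labels, diagonal_policy="defined",
                          meta={"normalized": normalized})


def _shortest_path_edges(weights: np.ndarray, lengths: np.ndarray,
                         dist: np.ndarray, i: int, j: int) -> list[tuple[int, int]]:
    """Edges of the length-shortest path i→j, ties broken by smallest next index."""
    path = []
    u = i
    n = weights.shape[0]
    for _ in range(n):
        if u == j:
            return path
        neigh = np.flatnonzero(weights[u] > 0)
        slack = lengths[u, neigh] + dist[neigh, j] - dist[u, j]
        on_path = neigh[np.isclose(slack, 0.0, rtol=1e-9, atol=1e-9)]
        if on_path.size == 0:  # pragma: no cover - guarded by connectivity check
            raise DisconnectedGraphError(f"no path from region {i} to {j}")
        v = int(on_path[0])  # neighbours sorted: smallest-index tie-break
        path.append((u, v))
        u = v
    raise RuntimeError("shortest-path reconstruction exceeded N steps")


def search_information_directed(c: Connectome, lengths=None) -> np.ndarray:
    """Directed search information SI(i→j) in bits.

    SI(i, j) = −log2 Π M along the shortest path from i to j on the length
    matrix (tract lengths if given, else reciprocal weights): the
    information a random walker needs to follow that path.  Zero on the
    diagonal; asymmetric in general (a leaf reaches a hub for free, the
    hub must choose).
    """
    w = c.weights
    if lengths is None:
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    else:
        lengths = np.asarray(lengths, dtype=float)
        if not np.array_equal(lengths > 0, w > 0):
            raise ValueError("lengths support does not match weights")
    m = transition_matrix(c)
    dist = dijkstra(csr_matrix(np.where(w > 0, lengths, 0.0)), directed=False)
    if not np.isfinite(dist).all():
        raise DisconnectedGraphError("graph is disconnected; no finite shortest paths")
    n = c.n_regions
    si = np.zeros((n, n))
    log2m = np.full_like(m, np.nan)
    pos = m > 0
    log2m[pos] = np.log2(m[pos])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            edges = _shortest_path_edges(w, lengths, dist, i, j)
            si[i, j] = -sum(log2m[u, v] for u, v in edges)
    return si


def search_information_matrix(c: Connectome, lengths=None) -> PairwiseMatrix:
    """Symmetrized search information: pairwise mean of SI(i→j) and SI(j→i).

    The directed matrix is kept in ``meta['directed']``.
    """
    si = search_information_directed(c, lengths)
    sym = (si + si.T) / 2.0
    return PairwiseMatrix(values=sym, metric_name="search_information_sym",
                          labels=c.labels, diagonal_policy="zero",
                          meta={"directed": si})


def structural_connectivity_matrix(c: Connectome) -> PairwiseMatrix:
    """The adjacency itself, wrapped for use as a comparison baseline."""
    return PairwiseMatrix(values=c.weights.copy(), metric_name="structural_connectivity",
                          labels=c.labels, diagonal_policy="zero")
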