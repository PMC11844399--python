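"""Connectome container, validation, and Laplacian machinery.

A structural connectome is a weighted, symmetric, zero-diagonal adjacency
matrix ``A`` whose entry ``A[i, j]`` counts the white-matter streamlines
(tracts) inferred between brain regions ``i`` and ``j``.  Everything else in
the package — random-walk metrics, the Ising simulator, the comparison
machinery — consumes the :class:`Connectome` built here.

The central linear-algebra object is the graph Laplacian (Kirchhoff matrix)
``Γ = D − A`` with ``D`` the diagonal of row sums (node strengths).  Its
Moore–Penrose pseudoinverse ``Γ⁺`` carries all hitting-time / commute-time
information for the random walk with transition matrix ``M = D⁻¹ A``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

WEIGHT_KINDS = ("count", "binary", "length")
HEMISPHERES = ("left", "right")


class ConnectomeValidationError(ValueError):
    """Raised when a raw matrix violates the connectome invariants."""


class DisconnectedGraphError(ValueError):
    """Raised when a metric requiring a connected graph meets a disconnected one."""


@dataclass(frozen=True)
class Connectome:
    """Validated structural connectivity matrix with region metadata.

    Attributes
    ----------
    weights
        ``(N, N)`` symmetric, non-negative, zero-diagonal float array.
    labels
        Region identifiers, length ``N``.
    hemisphere
        Per-region tag in ``{"left", "right"}``.  By convention the first
        half of the ordering is the left hemisphere, and the homotopic
        (contralateral) partner of region ``i`` is ``i + N/2``.
    weight_kind
        One of ``{"count", "binary", "length"}``.
    """

    weights: np.ndarray
    labels: tuple
    hemisphere: tuple
    weight_kind: str = "count"

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def left_indices(self) -> np.ndarray:
        return np.array([i for i, h in enumerate(self.hemisphere) if h == "left"])

    @property
    def right_indices(self) -> np.ndarray:
        return np.array([i for i, h in enumerate(self.hemisphere) if h == "right"])

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """Pairs ``(i, i + N/2)`` matching each left region with its right partner."""
        n = self.n_regions
        if n % 2:
            raise ValueError("homotopic pairing requires an even number of regions")
        half = n // 2
        return [(i, i + half) for i in range(half)]

    def with_weights(self, weights: np.ndarray, weight_kind: str | None = None,
                     tol: float = 1e-8) -> "Connectome":
        """Return a re-validated copy with new weights, same region metadata."""
        return validate_connectome(
            weights, labels=self.labels, hemisphere=self.hemisphere,
            weight_kind=weight_kind or self.weight_kind, tol=tol,
        )


@dataclass(frozen=True)
class DegreeDiagonal:
    """Row sums of the adjacency (node strengths), ``D_ii = Σ_k A_ik``."""

    values: np.ndarray

    @property
    def volume(self) -> float:
        """Total walk volume ``Σ_k D_kk`` (twice the total edge weight)."""
        return float(self.values.sum())


@dataclass(frozen=True)
class LaplacianOperator:
    """Graph Laplacian ``Γ = D − A`` with its pseudoinverse and rank.

    The pseudoinverse is computed by full symmetric eigendecomposition:
    eigenvalues above ``zero_tolerance × λ_max`` are inverted, the rest
    zeroed.  For a connected graph the rank is ``N − 1`` and the null space
    is spanned by the constant vector.
    """

    matrix: np.ndarray
    pseudoinverse: np.ndarray
    rank: int
    zero_tolerance: float


def _default_hemisphere(n: int) -> tuple:
    half = n // 2
    return tuple(["left"] * half + ["right"] * (n - half))


def validate_connectome(raw_matrix, labels=None, hemisphere=None, *,
                        weight_kind: str = "count", tol: float = 1e-8) -> Connectome:
    """Validate a raw matrix into a :class:`Connectome`.

    Symmetrizes only if the asymmetry is within ``tol`` (absolute); zeroes
    the diagonal with a logged warning if within ``tol``.  Anything beyond
    tolerance, a negative entry, or a non-square input is an error.
    """
    a = np.array(raw_matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ConnectomeValidationError(f"input must be square, got shape {a.shape}")
    n = a.shape[0]
    if n < 2:
        raise ConnectomeValidationError("a connectome needs at least 2 regions")
    if not np.isfinite(a).all():
        raise ConnectomeValidationError("non-finite entries in connectivity matrix")
    asym = np.abs(a - a.T).max()
    if asym > tol:
        raise ConnectomeValidationError(
            f"matrix asymmetry {asym:.3g} exceeds tolerance {tol:.3g}")
    a = (a + a.T) / 2.0
    diag_max = np.abs(np.diag(a)).max() if n else 0.0
    if diag_max > tol:
        raise ConnectomeValidationError(
            f"nonzero diagonal (max {diag_max:.3g}) exceeds tolerance {tol:.3g}; "
            "self-loops are not allowed")
    if diag_max > 0:
        logger.warning("zeroing near-zero diagonal entries (max %.3g)", diag_max)
    np.fill_diagonal(a, 0.0)
    if (a < 0).any():
        raise ConnectomeValidationError("negative weights are not allowed")
    if weight_kind not in WEIGHT_KINDS:
        raise ConnectomeValidationError(f"weight_kind must be one of {WEIGHT_KINDS}")

    if labels is None:
        labels = tuple(f"region_{i:03d}" for i in range(n))
    else:
        labels = tuple(str(x) for x in labels)
        if len(labels) != n:
            raise ConnectomeValidationError(
                f"{len(labels)} labels for {n} regions")
    if hemisphere is None:
        hemisphere = _default_hemisphere(n)
    else:
        hemisphere = tuple(str(x) for x in hemisphere)
        if len(hemisphere) != n:
            raise ConnectomeValidationError(
                f"{len(hemisphere)} hemisphere tags for {n} regions")
        if not set(hemisphere) <= set(HEMISPHERES):
            raise ConnectomeValidationError(
                f"hemisphere tags must be in {HEMISPHERES}")

    a.setflags(write=False)
    return Connectome(weights=a, labels=labels, hemisphere=hemisphere,
                      weight_kind=weight_kind)


def degree_diagonal(c: Connectome) -> DegreeDiagonal:
    """Node strengths ``D_ii = Σ_k A_ik``; errors on isolated regions."""
    values = c.weights.sum(axis=1)
    zero = np.flatnonzero(values == 0)
    if zero.size:
        bad = [c.labels[i] for i in zero[:5]]
        raise DisconnectedGraphError(
            f"regions with zero total weight {bad}; run prune_to_connected first")
    values.setflags(write=False)
    return DegreeDiagonal(values=values)


def laplacian(c: Connectome, zero_tolerance: float = 1e-10) -> LaplacianOperator:
    """Laplacian ``Γ = D − A`` and its pseudoinverse via eigendecomposition.

    Raises :class:`DisconnectedGraphError` when rank < N − 1: hitting times
    diverge between components, so downstream metrics would be meaningless.
    """
    deg = degree_diagonal(c)
    gamma = np.diag(deg.values) - c.weights
    evals, evecs = eigh(gamma)
    cutoff = zero_tolerance * max(evals.max(), 0.0)
    keep = evals > cutoff
    rank = int(keep.sum())
    n = c.n_regions
    if rank < n - 1:
        raise DisconnectedGraphError(
            f"Laplacian rank {rank} < N-1 = {n - 1}: graph is disconnected; "
            "run prune_to_connected first")
    inv_evals = np.where(keep, 1.0 / np.where(keep, evals, 1.0), 0.0)
    pinv = (evecs * inv_evals) @ evecs.T
    pinv = (pinv + pinv.T) / 2.0
    gamma.setflags(write=False)
    pinv.setflags(write=False)
    return LaplacianOperator(matrix=gamma, pseudoinverse=pinv, rank=rank,
                             zero_tolerance=zero_tolerance)


def prune_to_connected(c: Connectome) -> Connectome:
    """Induced sub-connectome on the largest connected component.

    Mirrors the removal of regions with zero inferred tracts: isolated or
    disconnected regions are dropped (and logged) before metric computation.
    Ties between equal-sized components go to the one containing the
    lowest region index.
    """
    n_comp, assignment = connected_components(
        csr_matrix(c.weights > 0), directed=False)
    if n_comp == 1:
        return c
    sizes = np.bincount(assignment, minlength=n_comp)
    best = int(np.flatnonzero(sizes == sizes.max())[0])
    keep = np.flatnonzero(assignment == best)
    if keep.size < 2:
        raise DisconnectedGraphError(
            "largest connected component has fewer than 2 regions")
    removed = [c.labels[i] for i in np.flatnonzero(assignment != best)]
    logger.info("pruning %d disconnected region(s): %s", len(removed), removed)
    sub = c.weights[np.ix_(keep, keep)]
    return validate_connectome(
        sub,
        labels=[c.labels[i] for i in keep],
        hemisphere=[c.hemisphere[i] for i in keep],
        weight_kind=c.weight_kind,
    )


def adjacency_variant(c: Connectome, mode: str, lengths=None) -> Connectome:
    """Alternative adjacency definitions for sensitivity analyses.

    ``density`` returns the input (streamline counts are the default
    weighting); ``binary`` maps every positive weight to 1; ``length``
    replaces each positive weight by the tract-length entry, which must
    share the exact nonzero support.
    """
    if mode == "density":
        return c
    if mode == "binary":
        return c.with_weights((c.weights > 0).astype(float), weight_kind="binary")
    if mode == "length":
        if lengths is None:
            raise ValueError("mode='length' requires a lengths matrix")
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != c.weights.shape:
            raise ValueError("lengths matrix shape mismatch")
        if not np.array_equal(lengths > 0, c.weights > 0):
            raise ValueError("lengths support (nonzero pattern) does not match weights")
        return c.with_weights(np.where(c.weights > 0, lengths, 0.0),
                              weight_kind="length")
    raise ValueError(f"unknown adjacency variant {mode!r}")
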