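"""Structure–function comparison machinery.

Quantifies how well a structural communication metric (commute time,
communicability, …) explains functional connectivity: Spearman rank
correlation over unordered region pairs, low-rank "top mode" reconstruction
of symmetric matrices to suppress measurement noise, a shuffled-structure
null, and the homotopic / random tract-addition perturbation experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.stats import spearmanr

from .graph_core import Connectome, validate_connectome
from .metrics import PairwiseMatrix

logger = logging.getLogger(__name__)

MASK_KINDS = ("all_offdiag", "intra_left", "intra_right", "inter_hemisphere", "custom")


@dataclass(frozen=True)
class PairMask:
    """A set of unordered, distinct region pairs to correlate over."""

    kind: str
    pairs: np.ndarray  # (P, 2) with pairs[:, 0] < pairs[:, 1]

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


@dataclass(frozen=True)
class ComparisonResult:
    """One structure–function comparison: ρ, p, and the settings that made it."""

    rho: float
    p_value: float
    n_pairs: int
    mask: str
    modes_x: int = 0
    modes_y: int = 0

    def as_dict(self) -> dict:
        return {"rho": self.rho, "p_value": self.p_value, "n_pairs": self.n_pairs,
                "mask": self.mask, "modes_x": self.modes_x, "modes_y": self.modes_y}


def _pairs_from_indices(idx: np.ndarray) -> np.ndarray:
    idx = np.asarray(idx)
    return np.array([(int(idx[a]), int(idx[b]))
                     for a in range(idx.size) for b in range(a + 1, idx.size)])


def all_offdiag_mask(n: int) -> PairMask:
    """Every unordered off-diagonal pair — the n·(n−1)/2 points of a scatter."""
    iu = np.triu_indices(n, k=1)
    return PairMask(kind="all_offdiag", pairs=np.column_stack(iu))


def hemisphere_mask(c: Connectome, kind: str) -> PairMask:
    """Pairs restricted by hemisphere: intra-left, intra-right, or inter."""
    if kind == "all_offdiag":
        return all_offdiag_mask(c.n_regions)
    left, right = c.left_indices, c.right_indices
    if kind == "intra_left":
        return PairMask(kind=kind, pairs=_pairs_from_indices(left))
    if kind == "intra_right":
        return PairMask(kind=kind, pairs=_pairs_from_indices(right))
    if kind == "inter_hemisphere":
        pairs = np.array(sorted((min(i, j), max(i, j)) for i in left for j in right))
        return PairMask(kind=kind, pairs=pairs)
    raise ValueError(f"unknown mask kind {kind!r}; expected one of {MASK_KINDS[:4]}")


def pair_mask(n: int, kind: str, hemisphere: Sequence[str] | None = None) -> PairMask:
    """Mask from a region count alone, using the first-half-left convention
    when no hemisphere tags are supplied."""
    from .graph_core import _default_hemisphere, validate_connectome

    hemisphere = hemisphere or _default_hemisphere(n)
    dummy = validate_connectome(np.ones((n, n)) - np.eye(n), hemisphere=hemisphere)
    return hemisphere_mask(dummy, kind)


def custom_mask(pairs: Sequence[tuple[int, int]]) -> PairMask:
    arr = np.array([(min(i, j), max(i, j)) for i, j in pairs])
    if (arr[:, 0] == arr[:, 1]).any():
        raise ValueError("self-pairs are not allowed in a PairMask")
    if len({tuple(p) for p in arr.tolist()}) != arr.shape[0]:
        raise ValueError("duplicate pairs in mask")
    return PairMask(kind="custom", pairs=arr)


def top_mode_reconstruction(m: PairwiseMatrix, k: int) -> PairwiseMatrix:
    """Rank-k reconstruction from the k largest-|eigenvalue| modes.

    Eigendecomposes the symmetric matrix itself (its "principal
    components"), keeps the k eigenpairs of largest absolute eigenvalue and
    returns ``Σ λ_r v_r v_rᵀ``.  ``meta`` records the retained eigenvalues
    and the fraction of total |eigenvalue| mass they carry.
    """
    n = m.n_regions
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    evals, evecs = eigh(m.values)
    order = np.argsort(np.abs(evals))[::-1]
    kept = order[:k]
    recon = (evecs[:, kept] * evals[kept]) @ evecs[:, kept].T
    recon = (recon + recon.T) / 2.0
    frac = float(np.abs(evals[kept]).sum() / np.abs(evals).sum())
    return PairwiseMatrix(values=recon, metric_name=m.metric_name,
                          labels=m.labels, diagonal_policy=m.diagonal_policy,
                          meta={"modes": k, "eigenvalues": evals[kept],
                                "variance_fraction": frac})


def spearman_compare(x: PairwiseMatrix, y: PairwiseMatrix,
                     mask: PairMask | None = None,
                     modes_x: int = 0, modes_y: int = 0) -> ComparisonResult:
    """Spearman ρ between two symmetric matrices over masked region pairs.

    ``modes_x`` / ``modes_y`` > 0 first replace the matrix by its top-k
    eigenmode reconstruction (0 keeps the full matrix).  Average ranks for
    ties; t-distribution p-value.
    """
    if x.values.shape != y.values.shape:
        raise ValueError("matrix dimension mismatch")
    if x.labels != y.labels:
        raise ValueError("matrix label mismatch")
    if mask is None:
        mask = all_offdiag_mask(x.n_regions)
    if mask.n_pairs < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    if modes_x:
        x = top_mode_reconstruction(x, modes_x)
    if modes_y:
        y = top_mode_reconstruction(y, modes_y)
    xv = x.offdiag_values(mask.pairs)
    yv = y.offdiag_values(mask.pairs)
    rho, p = spearmanr(xv, yv)
    return ComparisonResult(rho=float(rho), p_value=float(p),
                            n_pairs=mask.n_pairs, mask=mask.kind,
                            modes_x=modes_x, modes_y=modes_y)


def shuffled_connectome(c: Connectome, seed: int = 0) -> Connectome:
    """Permute upper-triangle weights uniformly; symmetry and diagonal preserved.

    The edge-weight multiset is exactly preserved, destroying topology
    while keeping the weight distribution — the null structure on which
    function is re-simulated.
    """
    rng = np.random.default_rng(seed)
    n = c.n_regions
    iu = np.triu_indices(n, k=1)
    vals = rng.permutation(c.weights[iu])
    w = np.zeros((n, n))
    w[iu] = vals
    w = w + w.T
    return validate_connectome(w, labels=c.labels, hemisphere=c.hemisphere,
                               weight_kind=c.weight_kind)


def add_homotopic_tracts(c: Connectome, added_weight: float) -> Connectome:
    """Add ``added_weight`` tracts between every homotopic pair (i, i+N/2)."""
    if added_weight <= 0:
        raise ValueError("added_weight must be > 0")
    w = c.weights.copy()
    for i, j in c.homotopic_pairs():
        w[i, j] += added_weight
        w[j, i] += added_weight
    return c.with_weights(w)


def homotopic_tract_sweep(c: Connectome, added_weights) -> list[Connectome]:
    """One perturbed connectome per requested homotopic weight."""
    return [add_homotopic_tracts(c, w) for w in added_weights]


def add_random_tracts(c: Connectome, added_weight: float, n_pairs: int,
                      seed: int = 0) -> Connectome:
    """Add ``added_weight`` to ``n_pairs`` random distinct non-homotopic pairs."""
    if n_pairs == 0:
        return c
    if added_weight <= 0:
        raise ValueError("added_weight must be > 0")
    n = c.n_regions
    homotopic = set(c.homotopic_pairs()) if n % 2 == 0 else set()
    candidates = [(i, j) for i in range(n) for j in range(i + 1, n)
                  if (i, j) not in homotopic]
    if n_pairs > len(candidates):
        raise ValueError(
            f"n_pairs={n_pairs} exceeds {len(candidates)} available non-homotopic pairs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_pairs, replace=False)
    w = c.weights.copy()
    for idx in chosen:
        i, j = candidates[idx]
        w[i, j] += added_weight
        w[j, i] += added_weight
    return c.with_weights(w)


def shuffled_structure_null(metric: PairwiseMatrix, c: Connectome,
                            simulate_fc: Callable[[Connectome, int], PairwiseMatrix],
                            n_shuffles: int = 20, seed: int = 0,
                            mask: PairMask | None = None) -> np.ndarray:
    """ρ distribution of the metric against FC simulated on shuffled structure.

    ``simulate_fc(connectome, seed)`` must return an FC PairwiseMatrix.
    Returns the n_shuffles Spearman coefficients; its 2.5/97.5 percentiles
    form the empirical null band.
    """
    ss = np.random.SeedSequence(seed)
    rhos = np.empty(n_shuffles)
    for k, child in enumerate(ss.spawn(n_shuffles)):
        s1, s2 = child.generate_state(2) % (2**31)
        c_shuf = shuffled_connectome(c, seed=int(s1))
        fc = simulate_fc(c_shuf, int(s2))
        rhos[k] = spearman_compare(metric, fc, mask=mask).rho
    return rhos
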