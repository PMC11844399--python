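"""Seeded generators of dMRI-like connectomes and structured FC matrices.

``generate_connectome`` emulates the qualitative features of a
tractography-derived structural matrix: sparse, non-negative, integer,
heavy-tailed (lognormal) streamline counts; two hemisphere blocks with
denser intra- than inter-hemisphere connectivity; optional homotopic edges
pairing region ``i`` with ``i + N/2``.  ``generate_structured_fc`` builds a
dense ground-truth FC whose pair ranking is exactly the (negated) commute
time of a connectome, plus controllable noise — a known answer for
pipeline-recovery tests.  Neither claims quantitative fidelity to any real
cohort; see docs/methods.md for what that does and does not buy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .graph_core import Connectome, validate_connectome
from .metrics import PairwiseMatrix, commute_time

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConnectomeRecipe:
    """Parameters of the synthetic connectome generator.

    Defaults target an 84-region (Desikan-Killiany-sized) connectome with
    sparse inter-hemispheric connectivity and heavy-tailed integer weights.
    """

    n_regions: int = 84
    intra_density: float = 0.35
    inter_density: float = 0.08
    weight_log_mean: float = 2.0
    weight_log_sd: float = 1.0
    homotopic_weight: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 2 or self.n_regions % 2:
            raise ValueError("n_regions must be an even integer ≥ 2")
        if not (0 < self.intra_density <= 1 and 0 < self.inter_density <= 1):
            raise ValueError("densities must be in (0, 1]")
        if self.inter_density >= self.intra_density:
            raise ValueError("inter_density must be < intra_density "
                             "(structural matrices are hemisphere-block sparse)")
        if self.homotopic_weight < 0:
            raise ValueError("homotopic_weight must be ≥ 0")
        if self.weight_log_sd < 0:
            raise ValueError("weight_log_sd must be ≥ 0")


def generate_connectome(recipe: ConnectomeRecipe) -> Connectome:
    """Draw a synthetic structural connectome; fully reproducible from seed.

    Edges are placed independently per pair at the block-appropriate
    density; weights are lognormal rounded up to positive integers
    (streamline-count-like).  If the result is disconnected, components are
    bridged with minimum-weight (1) edges between their lowest-index
    members, and the event is logged.
    """
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_regions
    half = n // 2
    hemi = np.array([0] * half + [1] * half)
    iu = np.triu_indices(n, k=1)
    intra = hemi[iu[0]] == hemi[iu[1]]
    density = np.where(intra, recipe.intra_density, recipe.inter_density)
    present = rng.random(iu[0].size) < density
    weights_flat = np.maximum(
        1, np.round(rng.lognormal(recipe.weight_log_mean, recipe.weight_log_sd,
                                  size=iu[0].size))).astype(float)
    w = np.zeros((n, n))
    w[iu] = np.where(present, weights_flat, 0.0)
    w = w + w.T
    if recipe.homotopic_weight > 0:
        for i in range(half):
            w[i, i + half] += recipe.homotopic_weight
            w[i + half, i] += recipe.homotopic_weight

    n_comp, assignment = connected_components(csr_matrix(w > 0), directed=False)
    if n_comp > 1:
        logger.info("bridging %d disconnected components with unit edges", n_comp)
        reps = [int(np.flatnonzero(assignment == k)[0]) for k in range(n_comp)]
        for a, b in zip(reps[:-1], reps[1:]):
            w[a, b] += 1.0
            w[b, a] += 1.0
    return validate_connectome(w, weight_kind="count")


def generate_structured_fc(c: Connectome, noise_sd: float = 0.3,
                           seed: int = 0) -> PairwiseMatrix:
    """Ground-truth FC: a decreasing function of commute time, plus noise.

    The noiseless target is the Gaussian kernel ``exp(−C_ij / 2σ²)`` with
    σ² the median off-diagonal commute time.  Because commute time is a
    squared Euclidean distance in the Laplacian-pseudoinverse embedding,
    this kernel is automatically a valid correlation matrix (positive
    semidefinite, unit diagonal) and is strictly decreasing in ``C`` — so
    at ``noise_sd = 0`` Spearman(FC, C) is exactly −1.  Symmetric Gaussian
    noise is then added and the result projected back to a correlation
    matrix (eigenvalue clipping + diagonal renormalization).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    ct = commute_time(c).values
    iu = np.triu_indices(c.n_regions, k=1)
    sigma2 = float(np.median(ct[iu]))
    fc = np.exp(-ct / (2.0 * sigma2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        n = c.n_regions
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        noise = (noise + noise.T) / np.sqrt(2.0)
        np.fill_diagonal(noise, 0.0)
        fc = fc + noise
        evals, evecs = np.linalg.eigh(fc)
        fc = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        d = np.sqrt(np.clip(np.diag(fc), 1e-12, None))
        fc = fc / np.outer(d, d)
        fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return PairwiseMatrix(values=fc, metric_name="fc", labels=c.labels,
                          diagonal_policy="defined",
                          meta={"noise_sd": noise_sd, "seed": seed,
                                "kernel_sigma2": sigma2})
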