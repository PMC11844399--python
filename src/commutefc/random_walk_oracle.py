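"""Independent verification of the analytic walk metrics.

Two routes that never touch the Laplacian pseudoinverse:

* a direct linear-system solution of the hitting-time recursion
  ``H_ij = Σ_k M_ik (1 + H_kj)`` — delete the target row/column of the
  transition matrix and solve ``(I − M̂) Ĥ = 1``;
* Monte-Carlo random walkers, first-order (memoryless) or second-order
  (non-backtracking: the walker may not immediately return to the node it
  just left, unless that is its only move).

These are test oracles, deliberately transparent rather than fast; the
simulated commute matrix is guarded to small graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve

from .graph_core import Connectome, DisconnectedGraphError
from .metrics import PairwiseMatrix, transition_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkEstimate:
    """Monte-Carlo estimate of a hitting time."""

    mean_steps: float
    std_error: float
    n_walks: int
    order: int
    seed: int


def brute_force_hitting_time(c: Connectome, target: int) -> np.ndarray:
    """Exact hitting times into ``target`` by solving ``(I − M̂) Ĥ = 1``.

    Returns an N-vector with a zero at the target itself.
    """
    n = c.n_regions
    if not 0 <= target < n:
        raise ValueError(f"target {target} out of range for N={n}")
    m = transition_matrix(c)
    keep = np.array([i for i in range(n) if i != target])
    m_hat = m[np.ix_(keep, keep)]
    try:
        h_hat = solve(np.eye(n - 1) - m_hat, np.ones(n - 1))
    except np.linalg.LinAlgError as exc:
        raise DisconnectedGraphError(
            "hitting-time system is singular: graph disconnected") from exc
    if not np.isfinite(h_hat).all() or (h_hat <= 0).any():
        raise DisconnectedGraphError(
            "hitting-time system produced non-physical values (disconnected graph?)")
    h = np.zeros(n)
    h[keep] = h_hat
    return h


def brute_force_hitting_matrix(c: Connectome) -> np.ndarray:
    """All-pairs hitting times from the linear-system oracle; H[i, j] into j."""
    n = c.n_regions
    h = np.zeros((n, n))
    for j in range(n):
        h[:, j] = brute_force_hitting_time(c, j)
    return h


def _step_order1(rng, cum_rows, cur):
    r = rng.random(cur.size)
    return (cum_rows[cur] > r[:, None]).argmax(axis=1)


def _step_order2(rng, weights, cur, prev):
    w = weights[cur].copy()
    has_prev = prev >= 0
    idx = np.flatnonzero(has_prev)
    w[idx, prev[idx]] = 0.0
    row_tot = w.sum(axis=1)
    # degree-1 intermediates: backtracking is the only move — restore it
    dead = np.flatnonzero(row_tot == 0)
    if dead.size:
        logger.debug("non-backtracking walker forced to backtrack at %d node(s)",
                     dead.size)
        w[dead, prev[dead]] = weights[cur[dead], prev[dead]]
        row_tot[dead] = w[dead].sum(axis=1)
    cum = np.cumsum(w, axis=1) / row_tot[:, None]
    r = rng.random(cur.size)
    return (cum > r[:, None]).argmax(axis=1)


def simulate_hitting_time(c: Connectome, source: int, target: int,
                          n_walks: int = 10_000, seed: int = 0, order: int = 1,
                          step_cap: int = 10**6) -> WalkEstimate:
    """Monte-Carlo hitting time from ``source`` to ``target``.

    ``order=1`` samples hops with probability ``A_ik / D_ii``; ``order=2``
    removes the previous node from the candidate set and renormalizes
    (non-backtracking), falling back to backtracking only at degree-1
    intermediates.  All walkers advance in lockstep (vectorized).
    """
    n = c.n_regions
    if not (0 <= source < n and 0 <= target < n) or source == target:
        raise ValueError("source and target must be distinct valid region indices")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    rng = np.random.default_rng(seed)
    weights = c.weights
    cum_rows = np.cumsum(weights, axis=1)
    cum_rows = cum_rows / cum_rows[:, -1][:, None]
    cur = np.full(n_walks, source, dtype=np.int64)
    prev = np.full(n_walks, -1, dtype=np.int64)
    steps = np.zeros(n_walks, dtype=np.int64)
    done = np.zeros(n_walks, dtype=np.int64)  # recorded step counts
    active = np.arange(n_walks)
    n_steps = 0
    while active.size:
        n_steps += 1
        if n_steps > step_cap:
            raise RuntimeError(
                f"step cap {step_cap} exceeded with {active.size} walkers active")
        if order == 1:
            nxt = _step_order1(rng, cum_rows, cur)
        else:
            nxt = _step_order2(rng, weights, cur, prev)
        steps += 1
        hit = nxt == target
        if hit.any():
            done[active[hit]] = steps[hit]
        keep = ~hit
        active = active[keep]
        prev = cur[keep]
        cur = nxt[keep]
        steps = steps[keep]
    mean = float(done.mean())
    se = float(done.std(ddof=1) / np.sqrt(n_walks)) if n_walks > 1 else 0.0
    return WalkEstimate(mean_steps=mean, std_error=se, n_walks=n_walks,
                        order=order, seed=seed)


def simulated_commute_matrix(c: Connectome, n_walks: int = 1000, seed: int = 0,
                             order: int = 1, max_regions: int = 100) -> PairwiseMatrix:
    """Monte-Carlo commute matrix: simulate(i→j) + simulate(j→i) per pair.

    A test oracle only — guarded to ``N ≤ max_regions``.  Per-pair seeds are
    spawned from the master seed, so each entry is reproducible on its own.
    Per-entry standard errors live in ``meta['std_error']``.
    """
    n = c.n_regions
    if n > max_regions:
        raise ValueError(
            f"simulated_commute_matrix is an oracle for small graphs (N ≤ {max_regions})")
    ss = np.random.SeedSequence(seed)
    vals = np.zeros((n, n))
    errs = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s_ij, s_ji = ss.spawn(2)
            est_ij = simulate_hitting_time(
                c, i, j, n_walks=n_walks,
                seed=int(s_ij.generate_state(1)[0] % (2**31)), order=order)
            est_ji = simulate_hitting_time(
                c, j, i, n_walks=n_walks,
                seed=int(s_ji.generate_state(1)[0] % (2**31)), order=order)
            vals[i, j] = vals[j, i] = est_ij.mean_steps + est_ji.mean_steps
            errs[i, j] = errs[j, i] = float(
                np.hypot(est_ij.std_error, est_ji.std_error))
    return PairwiseMatrix(values=vals, metric_name=f"simulated_commute_order{order}",
                          labels=c.labels, diagonal_policy="zero",
                          meta={"std_error": errs, "n_walks": n_walks,
                                "order": order, "seed": seed})
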