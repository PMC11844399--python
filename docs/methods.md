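# Methods

## Signalling model

The package models brain signalling as a first-order Markov walk on the
structural connectome. The state is the region currently holding the
signal; the transition probability from region *i* to *k* is
`M_ik = A_ik / D_ii`, the share of *i*'s streamlines that lead to *k*. The
walk has no global knowledge of the network — each step depends only on the
local tract counts — which is the physical assumption behind using commute
time as a communication metric.

All hitting/commute quantities reduce to linear algebra on the graph
Laplacian `Γ = D − A`:

* `H_ij = Σ_k (Γ⁺_ik − Γ⁺_ji − Γ⁺_jk + Γ⁺_jj) D_kk` (expected steps i → j),
* `C_ij = H_ij + H_ji = (Γ⁺_ii + Γ⁺_jj − 2 Γ⁺_ij) Σ_k D_kk`.

`Γ⁺` is computed by full symmetric eigendecomposition with a relative
eigenvalue cutoff (default 1e−10 × the largest eigenvalue): deterministic,
rank-revealing, and O(N³) is immaterial at N ≤ ~1000 regions. A Laplacian
rank below N−1 means the graph is disconnected; hitting times diverge
between components, so this is a hard error, with `prune_to_connected`
(keep the largest component, log the removals) as the sanctioned fix —
mirroring the standard practice of dropping regions with zero inferred
tracts. Streamline counts enter raw (no pre-normalisation): the row sums
that define `M` are taken on the counts as given.

Two independent oracles guard the closed forms: a direct solve of the
recursion `H_ij = Σ_k M_ik (1 + H_kj)` (delete the target row/column,
solve `(I − M̂)Ĥ = 1`), and vectorized Monte-Carlo walkers. The
second-order (non-backtracking) walker removes the previous node from the
candidate set and renormalises; at a degree-1 intermediate, backtracking is
the only move and is allowed (and logged) — the alternative of aborting
would make tree-like graphs unusable. Third- and higher-order memory is out
of scope. Per-pair walker seeds are spawned from one master seed so every
matrix entry is reproducible in isolation.

## Comparator metrics

* **MFPT commute**: mean first passage times from the fundamental matrix
  `Z = (I − M + 1πᵀ)⁻¹`, `MFPT_ij = (Z_jj − Z_ij)/π_j` with
  `π_i = D_ii / Σ_k D_kk`, symmetrised as `MFPT + MFPTᵀ`. For this chain
  the fundamental-matrix passage time coincides with the hitting time, so
  the two commute routes agree to numerical precision — the value of the
  second route is that it shares no code or decomposition with the
  pseudoinverse path.
* **Communicability**: `exp(D^{−1/2} A D^{−1/2})`. The symmetric
  normalisation is adopted as the standard normalised-communicability
  convention (an elementwise `A_ij/√(D_ii D_jj)` reading is algebraically
  the same matrix); the unnormalised `exp(A)` sits behind a flag for
  sensitivity checks. Uniform weight rescaling cancels by construction.
* **Search information**: `SI(i→j) = −log₂ Π M` along the shortest path on
  the length matrix, so values are non-negative bits. Lengths default to
  reciprocal weights when no tract-length matrix is supplied; both options
  are exposed because either convention appears in practice. Shortest
  paths use Dijkstra distances with deterministic path reconstruction —
  among equally short next hops the smallest region index is taken — so SI
  is reproducible even with degenerate path lengths. The symmetric output
  is the pairwise mean of the two directions; the asymmetric matrix is kept
  in `meta["directed"]`.

Diagonal policy: hitting/commute/SI diagonals are zero and excluded from
all correlations; the communicability diagonal is a well-defined self-walk
term, computed but likewise excluded (comparisons always run over the
N(N−1)/2 unordered off-diagonal pairs).

## Ising simulation of function

Energy `E = −λ Σ_ij Ã_ij s_i s_j` over ordered pairs (each undirected edge
counted twice); temperature is absorbed into λ, so acceptance is
`min(1, e^{−ΔE})` and a single-spin flip that destabilises the system by
3λ is accepted with probability `e^{−3λ}`.

Protocol defaults: spins initialised uniformly at random; per step a
uniformly chosen set of ⌈0.15·N⌉ regions is proposed; 5000 steps; the whole
series (no burn-in discard) enters FC. Two proposal semantics are
implemented because the natural readings differ: `block` (default) accepts
or rejects the whole set with one Metropolis decision computed from the
joint ΔE; `sequential` applies Metropolis spin by spin within the set.
Both satisfy detailed balance with respect to the Boltzmann distribution;
the 2-node stationary-distribution test pins this down empirically.

`weight_normalization="mean_edge"` (default) divides weights by their mean
positive value so that λ has a comparable scale across connectomes; with
raw streamline counts the relevant λ range would shrink with the count
scale. The normalisation is recorded in output metadata. A λ-sweep helper
reports |magnetization| and susceptibility χ = N·Var(m); the susceptibility
peak locates the order–disorder transition, and the structure–function
analyses run "just below" it (0.9 × the peak λ), where simulated FC is most
structured. The mean-field starting guess for the sweep grid is
λ₀ = 1/(2⟨strength⟩).

BOLD conversion convolves each spin series causally with a canonical
double-gamma HRF (peak 6 s, undershoot 16 s, dispersions 1 s, undershoot
ratio 6, 32 s support) at 1 s per Ising step; both the step-to-seconds
mapping and the kernel parameters are configuration-exposed assumptions,
not fitted quantities. FC is the Pearson correlation of the convolved
series; a frozen (zero-variance) region is an error that names the region.

## Comparison machinery

Structure–function coupling is the Spearman ρ (average ranks for ties,
t-distribution p-value) between two symmetric matrices over a pair mask:
all off-diagonal pairs, intra-left, intra-right, or inter-hemisphere, under
the convention that the first half of the region ordering is the left
hemisphere and the homotopic partner of region *i* is *i + N/2*.

"Top mode" comparison eigendecomposes the symmetric matrix itself (not a
time-series PCA), ranks modes by |eigenvalue| and reconstructs
`Σ λ_r v_r v_rᵀ` over the retained modes. Because measurement noise spreads
over the whole spectrum while the structural signal concentrates in the
leading modes, comparing top-mode reconstructions suppresses noise; the
package asserts this directionally on synthetic data rather than claiming
any particular percentage improvement.

The null model permutes the upper-triangle weights uniformly (preserving
the weight multiset, destroying topology) and re-simulates function on the
shuffled structure; the empirical 2.5/97.5 percentiles over 20 shuffles
form the null band. Degree-preserving rewiring is a noted alternative left
unimplemented. p-values are reported raw, one per comparison, with no
multiple-testing correction.

Perturbation experiments add tracts either to every homotopic pair or to
randomly chosen non-homotopic pairs (matched budget), re-derive commute
times, and compare recovery of a homotopically structured target FC.

## Synthetic data

`generate_connectome` draws a two-block (hemisphere) Erdős–Rényi-style
graph: edges independently per pair at intra-/inter-block densities
(defaults 0.35 / 0.08 — inter-hemisphere connectivity is structurally much
sparser than intra), weights lognormal(μ=2, σ=1) rounded up to positive
integers for a streamline-count-like heavy tail, optional homotopic edges,
and unit-weight bridging of any disconnected components (logged). The
84-region default matches the Desikan-Killiany atlas size. These parameters
were chosen once for qualitative realism (sparse, heavy-tailed,
hemisphere-blocked); no claim of quantitative fidelity to any cohort is
made, and the generator deliberately omits known features of real data —
spatial embedding, distance-dependent connection probability, measured
tract lengths, inter-subject variability. Passing tests therefore
demonstrate internal consistency of the method chain, not empirical
performance on MRI data.

`generate_structured_fc` provides a known ground truth: the Gaussian kernel
`exp(−C_ij / 2σ²)` (σ² = median off-diagonal commute time). Since commute
time is a squared Euclidean distance in the `Γ⁺` embedding, this kernel is
automatically a valid correlation matrix and strictly decreasing in C, so
the noiseless FC has Spearman −1 against commute time by construction.
Symmetric Gaussian noise is then added and the matrix projected back to a
correlation matrix (eigenvalue clipping, diagonal renormalisation). The
Ising route (`simulate_fc`) is the dynamics-faithful alternative; both are
first-class.

## Numerical choices and limitations

* Validation tolerances: absolute 1e−8 for symmetry and diagonal noise
  (file round-trip scale), configurable; negative weights are always
  errors.
* Pseudoinverse cutoff 1e−10 relative; oracle agreement is asserted at
  1e−8 max-abs on random graphs with N ∈ [3, 30].
* Monte-Carlo error model: estimates carry standard errors; agreement is
  asserted at 3 SE. For Markov-chain occupancy tests the chain is thinned
  (stride 25 ≫ the ~2-step autocorrelation time) so the multinomial error
  model applies.
* Walkers carry a hard step cap (default 10⁶) to abort pathological walks.
* Problem sizes in the test and acceptance runs — 84-region connectomes,
  5000-step Ising traces, 10-seed sweeps, 20-shuffle nulls, 10⁵-walk
  Monte-Carlo ensembles — were chosen as the smallest ensembles at which
  the asserted effects are stable across seeds.
* The package stops at desk-scale synthetic analysis: no tractography, no
  imaging formats, no cohort statistics, no Wilson–Cowan or other
  multi-parameter neural-mass models, no HRF deconvolution.
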