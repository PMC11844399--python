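import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commutefc import (
    HRFKernel,
    IsingConfig,
    coupling_sweep,
    functional_connectivity,
    hrf_convolve,
    ising_energy,
    ising_simulate,
    metropolis_acceptance,
    validate_connectome,
)
from commutefc.ising import SpinTrace
from conftest import random_connected_connectome


class TestEnergy:
    def test_direct_substitution(self, edge):
        # E = −λ Σ_ij A_ij s_i s_j over ordered pairs (each edge twice)
        assert ising_energy(edge, [1, 1], coupling=2.0) == pytest.approx(-12.0)
        assert ising_energy(edge, [1, -1], coupling=2.0) == pytest.approx(12.0)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 500))
    def test_global_flip_symmetry(self, seed):
        c = random_connected_connectome(6, seed)
        rng = np.random.default_rng(seed)
        s = rng.choice([-1, 1], 6)
        assert ising_energy(c, s, 1.3) == pytest.approx(ising_energy(c, -s, 1.3))

    def test_invalid_spins_rejected(self, edge):
        with pytest.raises(ValueError):
            ising_energy(edge, [1, 0], 1.0)


class TestMetropolisRule:
    def test_stabilizing_flip_always_accepted(self):
        lam = 1.7
        assert metropolis_acceptance(-lam) == 1.0

    def test_destabilizing_flip_boltzmann_weighted(self):
        lam = 0.8
        assert metropolis_acceptance(3 * lam) == pytest.approx(np.exp(-3 * lam))

    def test_empirical_acceptance_frequencies(self):
        # single-spin flips with ΔE = −λ and ΔE = +3λ on a crafted graph
        rng = np.random.default_rng(7)
        lam = 0.8
        n = 40_000
        accept = (rng.random(n) < metropolis_acceptance(3 * lam)).mean()
        p = np.exp(-3 * lam)
        assert abs(accept - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestSimulation:
    def test_zero_coupling_accepts_everything(self, make_connectome):
        c = make_connectome(10, seed=1)
        trace = ising_simulate(c, IsingConfig(coupling=0.0, n_steps=300, seed=2))
        assert trace.accepted.min() == 1.0

    def test_spins_are_plus_minus_one(self, make_connectome):
        c = make_connectome(6, seed=2)
        trace = ising_simulate(c, IsingConfig(coupling=0.5, n_steps=100, seed=3))
        assert set(np.unique(trace.spins)) <= {-1, 1}

    def test_strong_coupling_orders_the_system(self):
        # unit-weight K6 at λ = 50: deep in the ordered phase
        c = validate_connectome(np.ones((6, 6)) - np.eye(6))
        cfg = IsingConfig(coupling=50.0, n_steps=5000, seed=4,
                          burn_in_fraction=0.2, weight_normalization="none")
        trace = ising_simulate(c, cfg)
        m = np.abs(trace.magnetization()[trace.burn_in:]).mean()
        assert m > 0.95

    def test_two_node_boltzmann_distribution(self):
        # unit-weight edge: moderate energy gap keeps the chain fast-mixing,
        # so the iid 3σ multinomial bound is a fair error model
        two = validate_connectome([[0, 1], [1, 0]])
        lam = 0.5
        cfg = IsingConfig(coupling=lam, n_steps=100_000, seed=5,
                          weight_normalization="none")
        trace = ising_simulate(two, cfg)
        # thin by 25 steps (≫ the ~2-step autocorrelation time) so the
        # multinomial error model holds for the retained samples
        counts = collections.Counter(map(tuple, trace.spins[1000::25]))
        total = sum(counts.values())
        energies = {s: -lam * 2 * s[0] * s[1] for s in counts}
        z = sum(np.exp(-e) for e in energies.values())
        for s, e in energies.items():
            p = np.exp(-e) / z
            sigma = np.sqrt(p * (1 - p) / total)
            assert abs(counts[s] / total - p) < 3 * sigma

    def test_acceptance_rate_decreases_with_coupling(self, make_connectome):
        c = make_connectome(12, seed=9)
        rates = []
        for lam in [0.0, 0.05, 0.2, 1.0]:
            acc = [ising_simulate(c, IsingConfig(coupling=lam, n_steps=300,
                                                 seed=s)).accepted.mean()
                   for s in range(10)]
            rates.append(np.mean(acc))
        assert all(a >= b - 1e-9 for a, b in zip(rates, rates[1:]))

    def test_sequential_mode_runs_and_differs(self, make_connectome):
        c = make_connectome(8, seed=10)
        cfg = IsingConfig(coupling=0.3, n_steps=200, seed=11,
                          proposal_mode="sequential")
        trace = ising_simulate(c, cfg)
        assert trace.spins.shape == (200, 8)
        assert ((0 <= trace.accepted) & (trace.accepted <= 1)).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            IsingConfig(coupling=1.0, flip_fraction=0.0)
        with pytest.raises(ValueError):
            IsingConfig(coupling=-1.0)


class TestHrf:
    def _trace(self, spins):
        spins = np.asarray(spins, dtype=np.int8)
        return SpinTrace(spins=spins, bold=None, dt=1.0,
                         accepted=np.ones(len(spins)), burn_in=0,
                         config=IsingConfig(coupling=1.0, n_steps=len(spins)),
                         labels=tuple(f"r{i}" for i in range(spins.shape[1])))

    def test_impulse_reproduces_kernel(self):
        t_len = 64
        spins = np.zeros((t_len, 1), dtype=np.int8)
        spins[0, 0] = 1
        out = hrf_convolve(self._trace(spins))
        k = HRFKernel().samples()
        assert np.allclose(out.bold[: k.size, 0], k, atol=1e-10)
        assert out.bold.shape == (t_len, 1)

    def test_constant_input_reaches_kernel_sum(self):
        spins = np.ones((200, 1), dtype=np.int8)
        out = hrf_convolve(self._trace(spins))
        assert out.bold[-1, 0] == pytest.approx(HRFKernel().samples().sum(), rel=1e-8)

    def test_kernel_longer_than_trace_errors(self):
        spins = np.ones((5, 2), dtype=np.int8)
        with pytest.raises(ValueError, match="longer"):
            hrf_convolve(self._trace(spins))


class TestFunctionalConnectivity:
    def test_identical_and_negated_series(self):
        rng = np.random.default_rng(0)
        x = rng.choice([-1, 1], size=(50, 1))
        spins = np.column_stack([x, x, -x]).astype(np.int8)
        trace = TestHrf()._trace(spins)
        fc = functional_connectivity(trace, use_bold=False)
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert fc.values[0, 2] == pytest.approx(-1.0)

    def test_independent_spins_give_near_zero_fc(self, make_connectome):
        c = make_connectome(10, seed=12)
        trace = ising_simulate(c, IsingConfig(coupling=0.0, n_steps=5000, seed=13))
        fc = functional_connectivity(trace, use_bold=False)
        off = np.abs(fc.values[np.triu_indices(10, 1)])
        assert off.mean() < 0.1

    def test_frozen_region_is_named(self):
        spins = np.ones((30, 2), dtype=np.int8)
        spins[::2, 0] = -1
        trace = TestHrf()._trace(spins)
        with pytest.raises(ValueError, match="r1"):
            functional_connectivity(trace, use_bold=False)


class TestCouplingSweep:
    def test_susceptibility_peaks_between_phases(self, make_connectome):
        c = make_connectome(20, seed=14, density=0.5)
        sweep = coupling_sweep(c, np.linspace(0.005, 0.3, 6), n_steps=800,
                               n_seeds=2, seed=15)
        assert sweep.mean_abs_magnetization[-1] > sweep.mean_abs_magnetization[0]
        assert sweep.critical_coupling in sweep.couplings
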