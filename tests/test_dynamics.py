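"""Propagation, absorption statistics and the kinetic Monte Carlo oracle."""

import numpy as np
import pandas as pd
import pytest

import eetnet as e
from conftest import KBT300, random_trapped_system, two_state_network


def _chain_with_trap(rates=(1.0, 1.0), trap_rate=1.0):
    """Irreversible chain s0 -> s1 -> s2 -> trap."""
    n = len(rates) + 1
    K = np.zeros((n, n))
    for i, k in enumerate(rates):
        K[i + 1, i] = k
    states = pd.DataFrame(dict(
        state_id=[f"s{i}" for i in range(n)], subunit="X", monomer=1,
        pigment=[f"s{i}" for i in range(n)], energy_cm1=0.0, is_chl_a=True,
    ))
    net = e.KineticNetwork(states, K)
    sc = e.Scenario(network=net, traps=e.TrapSpec(
        donor_state_ids={1: (f"s{n-1}",)}, trap_rate=trap_rate))
    return e.build_generator(sc)


class TestPropagate:
    def test_t0_returns_initial_condition_exactly(self, mimic):
        ic = e.delta_initial_condition(mimic, "CP26_m1_00")
        traj = e.propagate(mimic, ic, np.array([0.0, 1.0]))
        assert np.array_equal(traj.populations[0], ic.weights)

    def test_two_state_closed_form(self):
        net = two_state_network()
        k_up = np.exp(-1)
        lam = 1.0 + k_up
        pi_b = k_up / (1.0 + k_up)
        ts = np.logspace(-3, 2, 60)
        traj = e.propagate(net, e.delta_initial_condition(net, "a"), ts)
        exact = pi_b * (1.0 - np.exp(-lam * ts))
        assert np.abs(traj.populations[:, 1] - exact).max() < 1e-9 * pi_b

    def test_closed_network_relaxes_to_boltzmann(self, mimic):
        ic = e.delta_initial_condition(mimic, "S-LHCII-B_m2_11")
        p = e.propagate(mimic, ic, np.array([1e6])).populations[0]
        assert np.abs(p - e.boltzmann_equilibrium(mimic)).max() < 1e-8

    def test_monotone_survival_with_sinks(self, mimic):
        sys = e.build_generator(e.Scenario(network=mimic, losses=e.LossSpec()))
        traj = e.propagate(sys, e.delta_initial_condition(sys, "CP29_m1_00"))
        assert np.all(np.diff(traj.survival) <= 1e-12)

    def test_descending_times_rejected(self, mimic):
        with pytest.raises(ValueError, match="ascending"):
            e.propagate(mimic, e.delta_initial_condition(mimic, "RC_m1_00"),
                        np.array([1.0, 0.5]))


class TestInitialConditions:
    def test_pigment_delta_site_basis(self, mimic):
        ic = e.initial_condition_for_pigment(mimic, "CT", monomer=1)
        j = np.argmax(ic.weights)
        assert mimic.states.loc[j, "pigment"] == "CT"
        assert mimic.states.loc[j, "monomer"] == 1
        assert ic.weights.sum() == 1.0

    def test_uniform_chl_a_spread(self, mimic):
        ic = e.uniform_chl_a_condition(mimic)
        n_a = int(mimic.states["is_chl_a"].sum())
        assert np.count_nonzero(ic.weights) == n_a
        assert ic.weights.max() == pytest.approx(1.0 / n_a)

    def test_localization_map_tie_breaks_to_lowest_index(self):
        net = two_state_network()
        loc = pd.DataFrame({"site1": [0.5, 0.5], "site2": [0.5, 0.5]})
        with pytest.warns(UserWarning, match="tie"):
            ic = e.initial_condition_for_pigment(net, "site1", localization_map=loc)
        assert ic.weights[0] == 1.0

    def test_localization_map_selects_most_localized(self):
        net = two_state_network()
        loc = pd.DataFrame({"site1": [0.9, 0.1], "site2": [0.1, 0.9]})
        ic = e.initial_condition_for_pigment(net, "site2", localization_map=loc)
        assert ic.weights[1] == 1.0

    def test_unknown_pigment_rejected(self, mimic):
        with pytest.raises(KeyError):
            e.initial_condition_for_pigment(mimic, "Chl z 999")

    def test_invalid_weight_vectors_rejected(self):
        with pytest.raises(ValueError):
            e.InitialCondition(np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            e.InitialCondition(np.array([-0.1, 1.1]))


class TestSplitting:
    def test_symmetric_start_splits_evenly(self, mimic):
        sys = e.build_generator(e.Scenario(network=mimic))
        w = np.zeros(sys.n_states)
        w[sys.index_of("M-LHCII-B_m1_06")] = 0.5
        w[sys.index_of("M-LHCII-B_m2_06")] = 0.5
        fate = e.splitting_probabilities(sys, e.InitialCondition(w))
        assert fate.p_trap1 == pytest.approx(0.5, abs=1e-9)
        assert fate.p_trap2 == pytest.approx(0.5, abs=1e-9)

    def test_single_trap_collects_all(self):
        sys = _chain_with_trap()
        fate = e.splitting_probabilities(sys, e.delta_initial_condition(sys, "s0"))
        assert fate.p_trap1 == pytest.approx(1.0, abs=1e-12)
        assert fate.p_fluor == fate.p_nonrad == 0.0

    def test_probabilities_sum_to_one_with_losses(self):
        sys, _ = random_trapped_system(3, with_losses=True)
        ic = e.delta_initial_condition(sys, "s0")
        fate = e.splitting_probabilities(sys, ic)
        total = fate.p_trap1 + fate.p_trap2 + fate.p_fluor + fate.p_nonrad
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_long_time_integration(self):
        sys, _ = random_trapped_system(5, with_losses=True)
        ic = e.delta_initial_condition(sys, "s1")
        fate = e.splitting_probabilities(sys, ic)
        traj = e.propagate(sys, ic, np.array([1e7]))
        assert np.abs(traj.sink_mass[0] - np.array(
            [fate.p_trap1, fate.p_trap2, fate.p_fluor, fate.p_nonrad])).max() < 1e-8

    def test_stranded_states_named_in_error(self):
        # two disconnected 2-state blocks, trap only on the first
        K = np.zeros((4, 4))
        K[1, 0] = K[0, 1] = 1.0
        K[3, 2] = K[2, 3] = 1.0
        states = pd.DataFrame(dict(
            state_id=["s0", "s1", "u0", "u1"], subunit="X", monomer=1,
            pigment=["s0", "s1", "u0", "u1"], energy_cm1=0.0, is_chl_a=True))
        net = e.KineticNetwork(states, K)
        sc = e.Scenario(network=net, traps=e.TrapSpec(donor_state_ids={1: ("s0",)}))
        with pytest.warns(UserWarning, match="cannot reach any sink"):
            sys = e.build_generator(sc)
        with pytest.raises(np.linalg.LinAlgError, match="u0"):
            e.splitting_probabilities(sys, e.delta_initial_condition(sys, "s1"))


class TestFirstPassageAndLifetime:
    def test_single_transient_state_mfpt_is_inverse_rate(self):
        sys = _chain_with_trap(rates=(), trap_rate=1.0)
        assert e.mean_first_passage_time(
            sys, e.delta_initial_condition(sys, "s0")) == pytest.approx(1.0)

    def test_irreversible_chain_sums_stage_means(self):
        sys = _chain_with_trap(rates=(1.0, 1.0), trap_rate=1.0)
        mfpt = e.mean_first_passage_time(sys, e.delta_initial_condition(sys, "s0"))
        assert mfpt == pytest.approx(3.0, rel=1e-12)

    def test_mfpt_requires_loss_free_system(self):
        sys, _ = random_trapped_system(2, with_losses=True)
        with pytest.raises(ValueError, match="without loss"):
            e.mean_first_passage_time(sys, e.delta_initial_condition(sys, "s0"))

    @pytest.mark.parametrize("seed", range(20))
    def test_mfpt_matches_survival_quadrature(self, seed):
        import scipy.integrate
        import scipy.linalg
        sys, _ = random_trapped_system(900 + seed)
        ic = e.delta_initial_condition(sys, "s2")
        mfpt = e.mean_first_passage_time(sys, ic)
        survival = lambda t: scipy.linalg.expm(sys.transient * t) @ ic.weights
        quad, _ = scipy.integrate.quad(lambda t: survival(t).sum(), 0, np.inf, limit=200)
        assert mfpt == pytest.approx(quad, rel=1e-3)

    def test_lifetime_single_state_nonradiative_only(self):
        states = pd.DataFrame(dict(state_id=["s0"], subunit="X", monomer=1,
                                   pigment=["s0"], energy_cm1=0.0, is_chl_a=True))
        net = e.KineticNetwork(states, np.zeros((1, 1)))
        sc = e.Scenario(network=net,
                        traps=e.TrapSpec(donor_state_ids={1: ("s0",)},
                                         open_monomers={1: False, 2: False}),
                        losses=e.LossSpec(mean_fluorescence_rate=0.0,
                                          nonradiative_rate=5e-4))
        sys = e.build_generator(sc)
        lt = e.excitation_lifetime(sys, e.delta_initial_condition(sys, "s0"))
        assert lt.mean_residence_ps == pytest.approx(2000.0)
        assert lt.tail_fit_ps == pytest.approx(2000.0, rel=1e-3)

    def test_lifetime_parallel_sinks_add_rates(self):
        states = pd.DataFrame(dict(state_id=["s0"], subunit="X", monomer=1,
                                   pigment=["s0"], energy_cm1=0.0, is_chl_a=True))
        net = e.KineticNetwork(states, np.zeros((1, 1)))
        ka, kb = 3e-3, 2e-3
        sc = e.Scenario(network=net,
                        traps=e.TrapSpec(donor_state_ids={1: ("s0",)},
                                         open_monomers={1: False, 2: False}),
                        losses=e.LossSpec(mean_fluorescence_rate=ka,
                                          nonradiative_rate=kb))
        sys = e.build_generator(sc)
        lt = e.excitation_lifetime(sys, e.delta_initial_condition(sys, "s0"))
        assert lt.mean_residence_ps == pytest.approx(1.0 / (ka + kb))


class TestGillespie:
    def test_deterministic_single_state_absorbs_at_rate(self):
        sys = _chain_with_trap(rates=(), trap_rate=2.0)
        res = e.gillespie_simulate(sys, e.delta_initial_condition(sys, "s0"),
                                   n_traj=4000, seed=1)
        assert res.fate_counts[0] == 4000
        assert abs(res.first_passage_mean - 0.5) < 3 * res.first_passage_se

    def test_fixed_seed_bit_identical(self):
        sys, _ = random_trapped_system(4)
        ic = e.delta_initial_condition(sys, "s0")
        a = e.gillespie_simulate(sys, ic, 500, seed=42)
        b = e.gillespie_simulate(sys, ic, 500, seed=42)
        assert np.array_equal(a.fate_counts, b.fate_counts)
        assert a.first_passage_mean == b.first_passage_mean

    def test_splitting_matches_linear_solve_within_3se(self):
        sys, _ = random_trapped_system(6, with_losses=True)
        ic = e.delta_initial_condition(sys, "s0")
        fate = e.splitting_probabilities(sys, ic)
        res = e.gillespie_simulate(sys, ic, 10_000, seed=7)
        exact = np.array([fate.p_trap1, fate.p_trap2, fate.p_fluor, fate.p_nonrad])
        se = np.sqrt(exact * (1 - exact) / res.n_traj)
        assert np.all(np.abs(res.fate_freq - exact) <= 3 * se + 1e-12)

    def test_checkpoint_occupancy_matches_propagation(self):
        sys, _ = random_trapped_system(8)
        ic = e.delta_initial_condition(sys, "s1")
        cps = [0.3, 1.0, 3.0, 10.0, 30.0]
        res = e.gillespie_simulate(sys, ic, 10_000, seed=11, checkpoint_times=cps)
        traj = e.propagate(sys, ic, np.array(cps))
        for k, c in enumerate(cps):
            exact = np.concatenate([traj.populations[k], traj.sink_mass[k]])
            freq = res.checkpoint_occupancy[c]
            se = np.sqrt(exact * (1 - exact) / res.n_traj)
            assert np.all(np.abs(freq - exact) <= 3 * se + 2e-3)
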