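"""Elementary rules of the lattice dynamics: initialization, infection law,
source selection, mutation, timers, and the synchronous-update contract."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sirsevo import (I_STATE, R_STATE, S_STATE, NeighbourhoodView, SimConfig,
                     Simulation, StrainTraits, infection_probability,
                     initialize, mutate, select_source)
from sirsevo.core import LatticeState, step


class TestStrainTraits:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            StrainTraits(0.0, 0.5)
        with pytest.raises(ValueError):
            StrainTraits(1.0, -0.1)
        with pytest.raises(ValueError):
            StrainTraits(float("nan"), 0.5)


class TestInitialize:
    def test_exact_infected_count(self):
        cfg = SimConfig(L=100, init_infected_fraction=0.05, seed=1)
        lat = initialize(cfg)
        counts = lat.counts()
        assert counts["I"] == 500
        assert counts["S"] == 9500
        assert counts["R"] == 0
        assert (lat.timer == 0).all()
        assert lat.time == 0.0
        b, t = lat.infected_traits()
        assert (b == cfg.init_strain.beta).all()
        assert (t == cfg.init_strain.tau_I).all()

    def test_full_infection_boundary(self):
        cfg = SimConfig(L=10, init_infected_fraction=1.0, seed=1)
        lat = initialize(cfg)
        assert lat.counts()["I"] == 100

    def test_seed_reproducibility(self):
        cfg = SimConfig(L=30, seed=7)
        a, b = initialize(cfg), initialize(cfg)
        assert (a.state == b.state).all()
        assert (a.beta == b.beta).all()

    def test_too_small_fraction_rejected(self):
        cfg = SimConfig(L=10, init_infected_fraction=0.001)
        with pytest.raises(ValueError, match="no epidemic"):
            cfg.validate()


class TestInfectionProbability:
    def test_empty_neighbourhood(self):
        assert infection_probability(NeighbourhoodView(()), 0.01) == 0.0

    def test_single_neighbour_closed_form(self):
        p = infection_probability(NeighbourhoodView((1.0,)), 0.01)
        assert p == pytest.approx(1.0 - np.exp(-0.01))

    def test_sum_linearity(self):
        eight = infection_probability(NeighbourhoodView((0.7,) * 8), 0.01)
        one = infection_probability(NeighbourhoodView((8 * 0.7,)), 0.01)
        assert eight == pytest.approx(one)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            infection_probability(NeighbourhoodView((1.0, -0.5)), 0.01)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 50.0), min_size=0, max_size=8))
    def test_bounds_and_monotonicity(self, betas):
        p = infection_probability(NeighbourhoodView(tuple(betas)), 0.01)
        assert 0.0 <= p <= 1.0
        p_up = infection_probability(NeighbourhoodView(tuple(betas) + (1.0,)),
                                     0.01)
        assert p_up >= p


class TestSelectSource:
    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            select_source(NeighbourhoodView(()), rng)

    def test_linearized_ratio(self):
        q = NeighbourhoodView((1.0, 3.0)).q_m(0.01, linearized=True)
        assert q == pytest.approx([0.25, 0.75])

    def test_q_normalized_exact_form(self):
        view = NeighbourhoodView((0.5, 1.5, 4.0))
        q = view.q_m(0.01, linearized=False)
        assert q.sum() == pytest.approx(1.0)
        assert (q > 0).all()

    def test_empirical_frequencies_match_q(self, rng):
        # Monte-Carlo vs the closed-form weights, 3 binomial sigma
        view = NeighbourhoodView((1.0, 2.0, 5.0))
        n = 100_000
        q = view.q_m(0.01)
        counts = np.bincount([select_source(view, rng) for _ in range(n)],
                             minlength=3)
        for k in range(3):
            sigma = np.sqrt(n * q[k] * (1 - q[k]))
            assert abs(counts[k] - n * q[k]) < 3 * sigma

    def test_symmetric_uniform(self, rng):
        view = NeighbourhoodView((2.0,) * 8)
        assert view.q_m(0.01) == pytest.approx([1 / 8] * 8)


class TestMutate:
    def test_mu_zero_never_mutates(self, rng):
        cfg = SimConfig(mu=0.0)
        s = StrainTraits(1.0, 0.5)
        assert all(mutate(s, cfg, rng) is s for _ in range(100))

    def test_four_branches_uniform(self, rng):
        # conditional on mutating, (+,+), (+,-), (-,+), (-,-) each 1/4
        cfg = SimConfig(mu=1.0, dt=1.0, d_beta=0.1, d_tau=0.1)
        s = StrainTraits(1.0, 0.5)
        n = 100_000
        counts = {(1, 1): 0, (1, -1): 0, (-1, 1): 0, (-1, -1): 0}
        for _ in range(n):
            m = mutate(s, cfg, rng)
            counts[(int(np.sign(m.beta - s.beta)),
                    int(np.sign(m.tau_I - s.tau_I)))] += 1
        sigma = np.sqrt(n * 0.25 * 0.75)
        for v in counts.values():
            assert abs(v - n / 4) < 3 * sigma

    def test_positivity_rule_at_boundary(self, rng):
        # a trait whose decrement would go <= 0 stays put; the other moves
        cfg = SimConfig(mu=1.0, dt=1.0, d_beta=0.1, d_tau=0.1)
        s = StrainTraits(0.05, 0.5)  # beta - d_beta < 0
        seen_beta = set()
        for _ in range(200):
            m = mutate(s, cfg, rng)
            seen_beta.add(round(m.beta, 9))
            assert m.beta > 0 and m.tau_I > 0
        assert seen_beta <= {0.05, 0.15}  # never 0.05 - 0.1


def _single_site_lattice(L, tau_I, beta=1.0):
    lat = LatticeState(state=np.zeros((L, L), dtype=np.int8),
                       timer=np.zeros((L, L), dtype=np.int64),
                       beta=np.zeros((L, L)), tau=np.zeros((L, L)))
    lat.state[L // 2, L // 2] = I_STATE
    lat.beta[L // 2, L // 2] = beta
    lat.tau[L // 2, L // 2] = tau_I
    return lat


class TestStep:
    def test_absorbing_without_infected(self, small_config, seeded_kernel):
        cfg = small_config
        lat = LatticeState(state=np.zeros((8, 8), dtype=np.int8),
                           timer=np.zeros((8, 8), dtype=np.int64),
                           beta=np.zeros((8, 8)), tau=np.zeros((8, 8)))
        out = step(lat, cfg)
        assert (out.state == S_STATE).all()
        assert out.time == pytest.approx(cfg.dt)

    def test_single_site_timer_arithmetic(self, seeded_kernel):
        # tau_I = 0.05, dt = 0.01: I -> R at the first sweep whose pre-advance
        # timer satisfies t_j >= tau_I (sweep 6), then R -> S tau_R later.
        cfg = SimConfig(L=9, dt=0.01, tau_R=0.1, mu=0.0, init_strain=StrainTraits(1e-9, 0.05))
        lat = _single_site_lattice(9, tau_I=0.05, beta=1e-9)
        site = (4, 4)
        states = [int(lat.state[site])]
        for _ in range(25):
            lat = step(lat, cfg)
            states.append(int(lat.state[site]))
        i_sweeps = sum(1 for s in states[1:] if s == I_STATE) + 0
        # residence: checks at timer 0..5 -> leaves I on the 6th sweep
        assert states[1:6] == [I_STATE] * 5
        assert states[6] == R_STATE
        # R residence: timer 0..10 -> leaves R 11 sweeps later
        assert states[7:17] == [R_STATE] * 10
        assert states[17] == S_STATE

    def test_transition_legality_and_conservation(self):
        cfg = SimConfig(L=20, seed=3, init_strain=StrainTraits(1.2, 0.5))
        sim = Simulation(cfg)
        allowed = {(S_STATE, S_STATE), (S_STATE, I_STATE),
                   (I_STATE, I_STATE), (I_STATE, R_STATE),
                   (R_STATE, R_STATE), (R_STATE, S_STATE)}
        for _ in range(600):
            before = sim.lattice.state.copy()
            sim.sweep()
            after = sim.lattice.state
            pairs = set(zip(before.reshape(-1).tolist(),
                            after.reshape(-1).tolist()))
            assert pairs <= allowed
            c = sim.lattice.counts()
            assert c["S"] + c["I"] + c["R"] == 400

    def test_strain_set_never_grows_without_mutation(self):
        cfg = SimConfig(L=20, mu=0.0, seed=5, init_strain=StrainTraits(1.0, 0.5))
        sim = Simulation(cfg)
        # hand-plant a second strain
        lat = sim.lattice
        lat.state[0, 0] = I_STATE
        lat.beta[0, 0] = 2.0
        lat.tau[0, 0] = 0.3
        lat.timer[0, 0] = 0
        initial = {(1.0, 0.5), (2.0, 0.3)}
        for _ in range(20):
            for _ in range(50):
                sim.sweep()
            b, t = sim.lattice.infected_traits()
            assert set(zip(b.tolist(), t.tolist())) <= initial

    def test_superinfection_exclusion(self):
        # an infected site's strain never changes while it stays infected
        cfg = SimConfig(L=16, mu=0.0, seed=9, init_strain=StrainTraits(1.5, 0.5))
        sim = Simulation(cfg)
        lat = sim.lattice
        lat.beta[lat.state == I_STATE] = np.linspace(
            1.0, 2.0, int(lat.n_infected))  # all distinct
        for _ in range(400):
            before_state = sim.lattice.state.copy()
            before_beta = sim.lattice.beta.copy()
            sim.sweep()
            stayed = (before_state == I_STATE) & (sim.lattice.state == I_STATE)
            assert (sim.lattice.beta[stayed] == before_beta[stayed]).all()


class TestRunContract:
    def test_t_max_zero_returns_initial(self):
        cfg = SimConfig(L=12, seed=2)
        sim = Simulation(cfg)
        before = sim.lattice.copy()
        traj, term = sim.run(0.0)
        assert term == "t_max"
        assert (sim.lattice.state == before.state).all()
        assert sim.lattice.time == 0.0

    def test_extinction_flag_iff_no_infected(self):
        # strong subcritical strain -> certain extinction
        cfg = SimConfig(L=16, mu=0.0, seed=4, init_strain=StrainTraits(0.01, 0.05))
        sim = Simulation(cfg)
        traj, term = sim.run(50.0)
        assert term == "extinction"
        assert sim.lattice.n_infected == 0

    def test_seed_determinism_bit_exact(self):
        cfg = SimConfig(L=24, seed=11, init_strain=StrainTraits(1.2, 0.5))
        results = []
        for _ in range(2):
            sim = Simulation(cfg)
            traj, _ = sim.run(20.0)
            results.append((sim.lattice, traj.frame))
        a, b = results
        assert (a[0].state == b[0].state).all()
        assert (a[0].timer == b[0].timer).all()
        assert (a[0].beta == b[0].beta).all()
        assert a[1].equals(b[1])

    def test_different_seeds_differ(self):
        lat1 = Simulation(SimConfig(L=24, seed=1))
        lat2 = Simulation(SimConfig(L=24, seed=2))
        lat1.run(10.0)
        lat2.run(10.0)
        assert (lat1.lattice.state != lat2.lattice.state).any()

    def test_trajectory_invariants(self):
        cfg = SimConfig(L=20, seed=6, init_strain=StrainTraits(1.2, 0.5))
        sim = Simulation(cfg)
        traj, _ = sim.run(30.0, sample_every=0.5)
        f = traj.frame
        assert (np.diff(f["time"]) > 0).all()
        np.testing.assert_allclose(
            f[["frac_S", "frac_I", "frac_R"]].sum(axis=1), 1.0, atol=1e-12)


class TestInfectionLawKernel:
    def test_per_site_frequency_matches_closed_form(self):
        """Over many single-sweep replicates of a frozen lattice, per-site
        infection frequency matches 1 - exp(-dt * sum beta) within 3 sigma,
        grouping S sites by their infected-neighbour count."""
        from sirsevo.io import FixtureSpec, generate_fixture
        lat, truth = generate_fixture(FixtureSpec(
            "frozen_lattice", {"L": 16, "frac_I": 0.25, "frac_R": 0.1,
                               "beta": 2.0, "tau_I": 5.0}, seed=8))
        cfg = SimConfig(L=16, dt=0.05, mu=0.0, init_strain=StrainTraits(2.0, 5.0))
        sim = Simulation(cfg, state=lat)
        base = lat
        # infected-neighbour count per S site via the Moore index maps
        nbr_inf = np.zeros((16, 16), dtype=int)
        for k in range(8):
            nbr_inf += (base.state[sim.nbr_r[:, :, k],
                                   sim.nbr_c[:, :, k]] == I_STATE)
        s_mask = base.state == S_STATE
        n_rep = 20_000
        hits = np.zeros((16, 16), dtype=int)
        for _ in range(n_rep):
            sim.lattice.state[:] = base.state
            sim.lattice.timer[:] = base.timer
            sim.lattice.beta[:] = base.beta
            sim.lattice.tau[:] = base.tau
            sim.sweep()
            hits += s_mask & (sim.lattice.state == I_STATE)
        exposed = s_mask & (nbr_inf > 0)
        assert not (hits[s_mask & (nbr_inf == 0)] > 0).any()
        p_site = 1.0 - np.exp(-cfg.dt * 2.0 * nbr_inf[exposed])
        obs = hits[exposed]
        z = (obs - n_rep * p_site) / np.sqrt(n_rep * p_site * (1 - p_site))
        # per-site 3-sigma violations no more frequent than chance allows
        assert np.mean(np.abs(z) > 3) <= 0.01
        # and the aggregate infection count matches the law within 3 sigma
        tot_mean = n_rep * p_site.sum()
        tot_sigma = np.sqrt((n_rep * p_site * (1 - p_site)).sum())
        assert abs(obs.sum() - tot_mean) < 3 * tot_sigma
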