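import numpy as np
import pytest
from scipy import stats

import replifire as rf
from tests.conftest import make_state


class TestInitAndCandidates:
    def test_initial_state_is_empty(self, mm1_params, small_lattice):
        state, _, _ = small_lattice
        assert state.f == 0.0
        assert state.nb == 0
        assert state.t == 0
        # available factors at t=0 equal N0
        assert mm1_params.factors_available(0, state.nb) == mm1_params.N0

    def test_size_mismatch_rejected(self, mm1_params):
        omap = rf.generate_origin_map(100, "continuous")
        mask = rf.generate_region_mask(50, 0.0, "block")
        with pytest.raises(ValueError):
            rf.init_state(mm1_params, omap, mask)

    def test_zero_probability_yields_no_candidates(self, rng, small_lattice):
        state, omap, mask = small_lattice
        p = rf.ModelParameters(Pout=0.0, variant="MM1")
        assert rf.candidate_blocks(state, p, omap, mask, rng).size == 0

    def test_probability_one_selects_every_block(self, rng, small_lattice):
        state, omap, mask = small_lattice
        p = rf.ModelParameters(Pout=1.0, variant="MM1")
        assert rf.candidate_blocks(state, p, omap, mask, rng).size == state.L

    def test_replicated_blocks_never_candidates(self, rng, small_lattice):
        state, omap, mask = small_lattice
        rf.force_fire(state, np.arange(0, 200, 2))
        p = rf.ModelParameters(Pout=1.0, variant="MM1")
        cand = rf.candidate_blocks(state, p, omap, mask, rng)
        assert np.all(state.blocks[cand] == 0)

    def test_candidate_count_matches_binomial_mean(self):
        """Fresh MM1 lattice: candidate count mean over seeds within 3 SD
        of the analytic binomial expectation L * Pout."""
        L, pout, n = 2000, 0.05, 1000
        p = rf.ModelParameters(Pout=pout, variant="MM1")
        omap = rf.generate_origin_map(L, "continuous")
        mask = rf.generate_region_mask(L, 0.0, "block")
        state = rf.init_state(p, omap, mask)
        rng = np.random.default_rng(3)
        counts = [
            rf.candidate_blocks(state, p, omap, mask, rng).size for _ in range(n)
        ]
        se = np.sqrt(L * pout * (1 - pout) / n)
        assert abs(np.mean(counts) - L * pout) < 3 * se


class TestForkProximalZone:
    def test_zero_distance_empty(self):
        state = make_state("0011100")
        assert rf.fork_proximal_zone(state, 0).sum() == 0

    def test_single_rightward_fork(self):
        # eye [2,5): right fork edge at block 4, zone = {5,6,7} for d=3
        state = make_state("0011100000")
        zone = rf.fork_proximal_zone(state, 3)
        assert set(np.flatnonzero(zone)) == {5, 6, 7} | {1, 0}  # left zone too

    def test_zone_truncated_at_lattice_end(self):
        state = make_state("0000000011")  # eye touches the right end
        zone = rf.fork_proximal_zone(state, 5)
        assert set(np.flatnonzero(zone)) == {3, 4, 5, 6, 7}

    def test_zone_truncated_at_next_eye(self):
        # two eyes separated by a 2-block gap; d=5 must not leak past eyes
        state = make_state("0110011000")
        zone = rf.fork_proximal_zone(state, 5)
        assert set(np.flatnonzero(zone)) == {0, 3, 4, 7, 8, 9}

    def test_zone_only_unreplicated(self):
        state = make_state("0011100")
        zone = rf.fork_proximal_zone(state, 10)
        assert not np.any(zone & (state.blocks == 1))


class TestFactorCap:
    def test_all_fire_when_under_cap(self, rng):
        state = make_state("0" * 50)
        p = rf.ModelParameters(N0=10, J=0)
        cand = np.arange(3)
        assert rf.apply_factor_cap(cand, state, p, rng).size == 3

    def test_cap_limits_firings(self, rng):
        state = make_state("0" * 200)
        p = rf.ModelParameters(N0=5, J=0)
        cand = np.arange(100)
        fired = rf.apply_factor_cap(cand, state, p, rng)
        assert fired.size == 5
        assert np.all(np.isin(fired, cand))

    def test_no_free_factors_no_firing(self, rng):
        state = make_state("0" * 50)
        state.fired_total = 5  # five factors bound, none released
        p = rf.ModelParameters(N0=5, J=0)
        assert rf.apply_factor_cap(np.arange(10), state, p, rng).size == 0


class TestPropagation:
    def test_symmetric_growth_two_blocks_per_round(self, rng):
        p = rf.ModelParameters(Pout=0.0, variant="MM1")
        state = make_state("0" * 21)
        rf.force_fire(state, [10])
        rf.fire_and_propagate(state, np.empty(0, int), p, rng)
        assert state.replicated_blocks == 3  # eye grew by 2 blocks

    def test_coalescence_drops_fork_count_by_two(self, rng):
        p = rf.ModelParameters(Pout=0.0, variant="MM1")
        state = make_state("0011001100")  # two eyes, 2-block gap
        forks_before = state.boundary_count
        rf.fire_and_propagate(state, np.empty(0, int), p, rng)
        rf.release_factors(state)
        assert state.boundary_count == forks_before - 2

    def test_mm2_mean_displacement(self):
        """MM2 fork speed drawn from {0,1,2,3} kb/min: mean eye growth per
        round is 2 * 1.5 kb/min * 2 min = 6 blocks."""
        p = rf.ModelParameters(Pout=0.0, variant="MM2")
        rng = np.random.default_rng(11)
        growths = []
        for _ in range(400):
            state = make_state("0" * 101)
            rf.force_fire(state, [50])
            before = state.replicated_blocks
            rf.fire_and_propagate(state, np.empty(0, int), p, rng)
            growths.append(state.replicated_blocks - before)
        mean = np.mean(growths)
        se = np.std(growths) / np.sqrt(len(growths))
        assert abs(mean - 6.0) < 3 * se

    def test_mm2_zero_draw_stalls(self):
        p = rf.ModelParameters(Pout=0.0, variant="MM2", speed_choices=(0.0,))
        rng = np.random.default_rng(0)
        state = make_state("0011100")
        rf.fire_and_propagate(state, np.empty(0, int), p, rng)
        assert state.replicated_blocks == 3


class TestRelease:
    def test_coalescence_releases_one_factor(self, rng):
        p = rf.ModelParameters(Pout=0.0)
        state = make_state("001101100")
        state.fired_total = 2
        rf.fire_and_propagate(state, np.empty(0, int), p, rng)
        rf.release_factors(state)
        assert state.nb == 1
        assert state.released_total == 1

    def test_two_end_terminations_release_one_factor(self):
        state = make_state("1111111")  # single eye spanning the lattice
        state.fired_total = 1
        rf.release_factors(state)
        assert state.nb == 0
        assert state.released_total == 1

    def test_full_replication_conserves_factors(self):
        p = rf.ModelParameters(N0=30, J=2, Pout=5e-3, variant="MM1")
        traj = rf.run_simulation(p, 2000, 4)
        assert traj.f[-1] == 1.0
        assert traj.fired_total == traj.released_total


class TestStepAndRun:
    def test_no_factors_only_time_advances(self, rng, small_lattice):
        state, omap, mask = small_lattice
        p = rf.ModelParameters(N0=0, J=0, Pout=1.0)
        rf.step(state, p, omap, mask, rng)
        assert state.t == 1 and state.f == 0.0

    def test_instant_completion(self, rng):
        L = 300
        p = rf.ModelParameters(N0=L, J=0, Pin=1.0, theta=1.0, Pout=1.0, variant="MM4")
        omap = rf.generate_origin_map(L, "continuous")
        mask = rf.generate_region_mask(L, 1.0, "block", rng)
        state = rf.init_state(p, omap, mask)
        rf.step(state, p, omap, mask, rng)
        assert state.f == 1.0

    def test_f_monotone_and_nb_bounded(self):
        p = rf.ModelParameters(N0=20, J=3, Pout=3e-3, variant="MM1")
        traj = rf.run_simulation(p, 5000, 9)
        assert np.all(np.diff(traj.f) >= 0)
        nmax = p.N0 + p.J * traj.rounds
        assert np.all(traj.nb >= 0) and np.all(traj.nb <= nmax)

    def test_round_cap_reported(self):
        p = rf.ModelParameters(N0=10, J=0, Pout=0.0, variant="MM1")
        with pytest.warns(RuntimeWarning, match="round cap"):
            traj = rf.run_simulation(p, 100, 0, max_rounds=5)
        assert not traj.completed
        assert traj.f[-1] == 0.0

    def test_same_seed_same_trajectory(self, mm1_params):
        a = rf.run_simulation(mm1_params, 2000, 42)
        b = rf.run_simulation(mm1_params, 2000, 42)
        assert np.array_equal(a.f, b.f)
        assert a.fired_total == b.fired_total

    def test_kjma_limit(self):
        """MM1, unlimited factors, continuous origins: f(t) follows the
        discrete nucleation-and-growth closed form."""
        L, pfire = 200_000, 2e-4
        p = rf.ModelParameters(N0=L, J=0, Pout=pfire, variant="MM1")
        traj = rf.run_simulation(p, L, 6)
        pred = rf.kjma_fraction(pfire, traj.rounds)
        assert np.max(np.abs(traj.f - pred)) < 0.02

    def test_binomial_firing_law_first_round(self):
        """Fresh lattice, one round, no factor cap: firings ~ Binomial(L, Pout)
        (chi-squared against the exact pmf over many seeds)."""
        L, pout, n = 400, 0.02, 3000
        p = rf.ModelParameters(N0=L, J=0, Pout=pout, variant="MM1")
        omap = rf.generate_origin_map(L, "continuous")
        mask = rf.generate_region_mask(L, 0.0, "block")
        rng = np.random.default_rng(21)
        counts = np.empty(n, int)
        for i in range(n):
            state = rf.init_state(p, omap, mask)
            _, n_init, _, _ = rf.step(state, p, omap, mask, rng)
            counts[i] = n_init
        edges = np.arange(counts.min(), counts.max() + 2)
        obs, _ = np.histogram(counts, bins=edges)
        exp = stats.binom.pmf(edges[:-1], L, pout) * n
        keep = exp > 5
        chi2 = np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep])
        assert chi2 < stats.chi2.ppf(0.99, df=keep.sum() - 1)


class TestReductionEquivalences:
    """Variant reductions agree in distribution (mean f(t) within 2 MC SE)."""

    @staticmethod
    def _mean_curves(pa, pb, L=4000, n_seeds=60, rounds=200):
        fa = np.zeros((n_seeds, rounds + 1))
        fb = np.zeros((n_seeds, rounds + 1))
        for i in range(n_seeds):
            ta = rf.run_simulation(pa, L, 1000 + i)
            tb = rf.run_simulation(pb, L, 5000 + i)
            fa[i, : ta.f.size] = ta.f
            fa[i, ta.f.size:] = 1.0
            fb[i, : tb.f.size] = tb.f
            fb[i, tb.f.size:] = 1.0
        return fa, fb

    @staticmethod
    def _assert_close(fa, fb):
        ma, mb = fa.mean(0), fb.mean(0)
        se = np.sqrt(fa.var(0) / fa.shape[0] + fb.var(0) / fb.shape[0])
        active = se > 0
        assert np.all(np.abs(ma - mb)[active] <= 2 * se[active] + 1e-12)

    def test_mm4_theta_one_equals_mm1(self):
        pin = 3e-3
        pa = rf.ModelParameters(N0=25, J=2, Pin=pin, theta=1.0, Pout=0.5, variant="MM4")
        pb = rf.ModelParameters(N0=25, J=2, Pout=pin, variant="MM1")
        self._assert_close(*self._mean_curves(pa, pb))

    def test_mm3_plocal_equals_pout_equals_mm1(self):
        pout = 3e-3
        pa = rf.ModelParameters(N0=25, J=2, Pout=pout, Plocal=pout, d=20, variant="MM3")
        pb = rf.ModelParameters(N0=25, J=2, Pout=pout, variant="MM1")
        self._assert_close(*self._mean_curves(pa, pb))

    def test_mm2_constant_draw_equals_mm1(self):
        pa = rf.ModelParameters(N0=25, J=2, Pout=3e-3, variant="MM2",
                                speed_choices=(0.5,))
        pb = rf.ModelParameters(N0=25, J=2, Pout=3e-3, variant="MM1")
        self._assert_close(*self._mean_curves(pa, pb))
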