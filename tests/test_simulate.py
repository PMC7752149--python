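"""Runs, ensembles and the exact Markov-chain oracle."""

import numpy as np
import pytest

import hepatoca as hc


def p_unit(**kw):
    base = dict(alpha=0.25, beta=0.25, gamma=0.25, dt=0.25)
    base.update(kw)
    return hc.Parameters(**base)


class TestExactOracle:
    def test_single_stressed_cell_geometric_absorption(self):
        # death is the only applicable rule: all-dead with probability 1
        # and expected time gamma (geometric with mean dt/P_d)
        lat = hc.build_chain(1)
        init = hc.TissueState(np.array([1], dtype=np.uint8))
        res = hc.exact_absorption(lat, hc.Parameters(5, 5, 2.5, dt=0.25), init)
        assert res.p_death == pytest.approx(1.0)
        assert res.p_recover == 0.0
        assert res.expected_time == pytest.approx(2.5)

    def test_two_sites_deterministic_death(self):
        lat = hc.build_chain(2)
        init = hc.TissueState(np.array([0, 1], dtype=np.uint8))
        res = hc.exact_absorption(lat, p_unit(), init)
        assert res.p_death == pytest.approx(1.0)
        assert res.expected_time == pytest.approx(0.5)  # two steps of 0.25 h

    def test_state_space_cap_refused(self):
        lat = hc.build_chain(4)
        init = hc.init_pericentral(lat, hc.InitSpec("pericentral_count", stressed_count=2))
        with pytest.raises(ValueError, match="max_states"):
            hc.exact_absorption(lat, hc.Parameters(1, 1, 1, dt=0.25), init, max_states=3)

    @pytest.mark.parametrize("engine", ["numpy", "numba"])
    def test_monte_carlo_agrees_with_linear_solve(self, engine):
        """N = 3 chain (H,S,H): absorption split from the enumerated kernel
        matches 10,000 Monte-Carlo replicas within 3 standard errors."""
        lat = hc.build_chain(3)
        init = hc.TissueState(np.array([0, 1, 0], dtype=np.uint8))
        params = hc.Parameters(1.0, 1.0, 1.0, dt=0.25)
        exact = hc.exact_absorption(lat, params, init)
        assert exact.p_recover + exact.p_death == pytest.approx(1.0)

        n_rep = 10_000
        ens = hc.run_ensemble(lat, init, params, n_rep, 2024, t_max=2000, engine=engine)
        p_hat = ens.outcome_counts["recovered"] / n_rep
        se = np.sqrt(exact.p_recover * (1 - exact.p_recover) / n_rep)
        assert abs(p_hat - exact.p_recover) < 3 * se

    @pytest.mark.parametrize("engine", ["numpy", "numba"])
    def test_oracle_with_division_cap(self, engine):
        """Division bookkeeping: capped N = 2 chain (H,D) can only ever
        place one daughter, so recovery is certain and bounded."""
        lat = hc.build_chain(2)
        init = hc.TissueState(np.array([0, 2], dtype=np.uint8))
        params = hc.Parameters(0.5, 5, 5, dt=0.25, division_cap=1)
        exact = hc.exact_absorption(lat, params, init)
        assert exact.p_recover == pytest.approx(1.0)
        ens = hc.run_ensemble(lat, init, params, 2000, 7, t_max=500, engine=engine)
        assert ens.outcome_counts["recovered"] == 2000
        assert all(r.new_cells == 1 for r in ens.runs)


class TestRunSingle:
    def test_all_dead_start_is_absorbing(self, chain10):
        init = hc.TissueState(np.full(10, 2, dtype=np.uint8))
        traj, res = hc.run_single(chain10, init, p_unit(), 1, t_max=100)
        assert res.outcome == "died"
        assert res.t_absorb == 0.0
        assert res.new_cells == 0

    def test_trajectory_conserves_and_monotone(self, chain10, damage40):
        params = hc.Parameters(5, 5, 5, dt=0.25)
        traj, res = hc.run_single(chain10, damage40, params, 3, t_max=2000)
        assert (traj.counts.sum(axis=1) == 10).all()
        assert (np.diff(traj.divisions_cum) >= 0).all()
        assert (np.diff(traj.times) > 0).all()
        assert res.min_h <= 6 <= res.max_h

    def test_deep_recovery_region(self, chain10, damage40):
        # gamma = dt: every stressed cell dies in the first step
        params = hc.Parameters(5, 5, 0.25, dt=0.25)
        traj, res = hc.run_single(chain10, damage40, params, 11, t_max=2000)
        assert traj.counts[1, 1] == 0
        assert res.outcome == "recovered"

    def test_t_max_below_dt_rejected(self, chain10, damage40):
        with pytest.raises(ValueError):
            hc.run_single(chain10, damage40, p_unit(), 1, t_max=0.1)


class TestDeterminism:
    def test_single_run_bitwise_reproducible(self, chain10, damage40):
        params = hc.Parameters(5, 5, 5, dt=0.25)
        t1, r1 = hc.run_single(chain10, damage40, params, 42, t_max=500)
        t2, r2 = hc.run_single(chain10, damage40, params, 42, t_max=500)
        assert (t1.counts == t2.counts).all()
        assert r1 == r2

    @pytest.mark.parametrize("engine", ["numpy", "numba"])
    def test_ensemble_reproducible(self, chain10, damage40, engine):
        params = hc.Parameters(5, 5, 7, dt=0.25)
        a = hc.run_ensemble(chain10, damage40, params, 50, 9, t_max=500, engine=engine)
        b = hc.run_ensemble(chain10, damage40, params, 50, 9, t_max=500, engine=engine)
        assert a.survival_probability == b.survival_probability
        assert [r.min_h for r in a.runs] == [r.min_h for r in b.runs]


class TestEnsembleStatistics:
    def test_deep_recovery_certain(self, chain10, damage40):
        params = hc.Parameters(5, 5, 0.25, dt=0.25)
        ens = hc.run_ensemble(chain10, damage40, params, 100, 3, t_max=2000)
        assert ens.survival_probability == 1.0
        assert ens.outcome_counts == {"recovered": 100, "died": 0, "coexisting": 0}

    def test_survival_decreases_with_gamma(self, chain10, damage40):
        """At fixed alpha, beta, N and damage, ensemble survival declines
        across the scanned gamma values (statistical, 200 replicas)."""
        survs = []
        for gamma in [1.25, 11.25, 21.25]:
            params = hc.Parameters(5, 5, gamma, dt=0.25)
            ens = hc.run_ensemble(chain10, damage40, params, 200, 17, t_max=4000)
            survs.append(ens.survival_probability)
        assert survs[0] > survs[1] > survs[2]

    def test_coexistence_detected_in_2d(self):
        lat = hc.build_hex_lobule(6)
        init = hc.init_pericentral(lat, hc.InitSpec("pericentral_layers", stressed_layers=2))
        params = hc.Parameters(5, 5, 12.25, dt=0.25)
        ens = hc.run_ensemble(lat, init, params, 10, 5, t_max=600)
        assert ens.outcome_counts["coexisting"] > 0
        m = ens.steady_fractions_mean
        assert m is not None and sum(m) == pytest.approx(1.0, abs=1e-9)

    def test_recovery_time_with_onset_offset(self, chain10, damage40):
        params = hc.Parameters(5, 5, 0.25, dt=0.25)
        _, res = hc.run_single(chain10, damage40, params, 13, t_max=2000)
        assert res.outcome == "recovered"
        assert hc.recovery_time(res, onset_offset=2.0) == res.t_absorb + 2.0
        _, dead = hc.run_single(
            chain10, hc.TissueState(np.full(10, 2, dtype=np.uint8)), params, 1, t_max=100
        )
        assert hc.recovery_time(dead) is None

    def test_invalid_replica_count(self, chain10, damage40):
        with pytest.raises(ValueError):
            hc.run_ensemble(chain10, damage40, p_unit(), 0, 1)
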