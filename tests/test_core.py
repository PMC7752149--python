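"""Update rules: per-step probabilities, scheduler, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hepatoca as hc
from hepatoca.core import (
    CellState,
    batch_conversion_mask,
    batch_death_mask,
    batch_proliferation,
)

H, S, D = int(CellState.H), int(CellState.S), int(CellState.D)


class TestParameters:
    def test_derived_probabilities(self):
        p = hc.Parameters(alpha=20.0, beta=5.0, gamma=2.5, dt=0.25)
        assert p.p_p == 0.25 / 20.0
        assert p.p_c == 0.05
        assert p.p_d == 0.1

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha=-1, beta=5, gamma=5),
            dict(alpha=5, beta=5, gamma=5, dt=0.0),
            dict(alpha=5, beta=0.1, gamma=5, dt=0.25),  # dt > beta
            dict(alpha=5, beta=5, gamma=5, epsilon=1.5),
            dict(alpha=5, beta=5, gamma=5, division_cap=0),
            dict(alpha=5, beta=5, gamma=5, neighbor_order="third"),
            dict(alpha=5, beta=5, gamma=5, t_norm="none"),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            hc.Parameters(**kwargs)

    def test_boundary_dt_equals_timescale(self):
        p = hc.Parameters(alpha=0.25, beta=0.25, gamma=0.25, dt=0.25)
        assert p.p_p == p.p_c == p.p_d == 1.0


class TestConversionRule:
    def test_no_stressed_neighbors_never_converts(self, chain10, rng):
        state = hc.TissueState(np.full(10, H, dtype=np.uint8))
        params = hc.Parameters(alpha=0.25, beta=0.25, gamma=0.25, dt=0.25)
        states = np.tile(state.states, (5000, 1))
        mask = batch_conversion_mask(states, chain10, params, rng)
        assert not mask.any()

    def test_interface_rate_matches_p_c_times_fraction(self, chain10, rng):
        # sites (S,H,H,...): the interface cell has N_s = 1 of T = 2
        arr = np.full(10, H, dtype=np.uint8)
        arr[0] = S
        params = hc.Parameters(alpha=5, beta=5, gamma=5, dt=0.25)
        states = np.tile(arr, (40000, 1))
        mask = batch_conversion_mask(states, chain10, params, rng)
        rate = mask[:, 1].mean()
        expect = params.p_c * 0.5
        assert abs(rate - expect) < 4 * np.sqrt(expect / 40000)
        assert not mask[:, 2:].any()  # no stressed neighbor there

    def test_epsilon_gives_spontaneous_rate_p_c_eps(self, chain10, rng):
        arr = np.full(10, H, dtype=np.uint8)
        params = hc.Parameters(alpha=5, beta=5, gamma=5, dt=0.25, epsilon=0.1)
        states = np.tile(arr, (40000, 1))
        mask = batch_conversion_mask(states, chain10, params, rng)
        rate = mask.mean()
        expect = params.p_c * 0.1
        assert abs(rate - expect) < 4 * np.sqrt(expect / 400000)


class TestSecondOrderNeighborhood:
    def test_distance_two_stress_converts_only_with_extended_shell(self, hex4, rng):
        """A stressed cell two sites away can convert a healthy cell only
        when the conversion rule sees the second-order shell."""
        center = int(np.flatnonzero(hex4.layer_of == 2)[0])
        second = hex4.neighbors2[center][0]
        arr = np.full(hex4.n_sites, H, dtype=np.uint8)
        arr[second] = S
        states = np.tile(arr, (20000, 1))
        first_only = hc.Parameters(5, 5, 5, dt=0.25, neighbor_order="first")
        extended = hc.Parameters(5, 5, 5, dt=0.25, neighbor_order="first_and_second")
        m1 = batch_conversion_mask(states, hex4, first_only, np.random.default_rng(1))
        m2 = batch_conversion_mask(states, hex4, extended, np.random.default_rng(1))
        assert not m1[:, center].any()
        rate = m2[:, center].mean()
        t_center = len(hex4.neighbors1[center]) + len(hex4.neighbors2[center])
        expect = extended.p_c / t_center
        assert abs(rate - expect) < 4 * np.sqrt(expect / 20000)


class TestDeathRule:
    def test_rate_is_dt_over_gamma(self, rng):
        arr = np.full(10, S, dtype=np.uint8)
        params = hc.Parameters(alpha=5, beta=5, gamma=2.5, dt=0.25)
        states = np.tile(arr, (20000, 1))
        mask = batch_death_mask(states, params, rng)
        assert abs(mask.mean() - 0.1) < 4 * np.sqrt(0.1 * 0.9 / 200000)

    def test_gamma_equal_dt_kills_all(self, rng):
        arr = np.full(10, S, dtype=np.uint8)
        params = hc.Parameters(alpha=5, beta=5, gamma=0.25, dt=0.25)
        mask = batch_death_mask(np.tile(arr, (100, 1)), params, rng)
        assert mask.all()


class TestProliferationRule:
    def test_contact_inhibition(self, chain10, rng):
        # no empty site anywhere: no divisions at p_p = 1
        arr = np.full(10, H, dtype=np.uint8)
        params = hc.Parameters(alpha=0.25, beta=0.25, gamma=0.25, dt=0.25)
        states = np.tile(arr, (1000, 1))
        rr, pp, tt = batch_proliferation(
            states, states == D, np.zeros_like(states, dtype=np.int32),
            chain10, params, rng,
        )
        assert rr.size == 0

    def test_contested_site_single_winner_fair_split(self, rng):
        # two healthy cells flank one empty site; exactly one division per
        # step and each parent wins about half the time (the exhaustive
        # enumeration of shuffle-and-claim gives exactly 1/2)
        lat = hc.build_chain(3)
        arr = np.array([H, D, H], dtype=np.uint8)
        params = hc.Parameters(alpha=0.25, beta=0.25, gamma=0.25, dt=0.25)
        states = np.tile(arr, (20000, 1))
        rr, pp, tt = batch_proliferation(
            states, states == D, np.zeros_like(states, dtype=np.int32),
            lat, params, rng,
        )
        assert rr.size == 20000  # one division per replica
        assert (tt == 1).all()
        share = (pp == 0).mean()
        assert abs(share - 0.5) < 4 * np.sqrt(0.25 / 20000)

    def test_division_cap_blocks_exhausted_parents(self, rng):
        lat = hc.build_chain(3)
        arr = np.array([H, D, H], dtype=np.uint8)
        params = hc.Parameters(alpha=0.25, beta=0.25, gamma=0.25, dt=0.25, division_cap=1)
        states = np.tile(arr, (500, 1))
        divs = np.zeros_like(states, dtype=np.int32)
        divs[:, 0] = 1  # left parent exhausted
        rr, pp, tt = batch_proliferation(states, states == D, divs, lat, params, rng)
        assert (pp == 2).all()


class TestScheduler:
    def test_deterministic_two_site_cascade(self):
        # (H,S) with all probabilities 1: conversion and death resolve from
        # the snapshot, so step 1 gives (S,D) and step 2 the dead tissue
        lat = hc.build_chain(2)
        params = hc.Parameters(alpha=0.25, beta=0.25, gamma=0.25, dt=0.25)
        state = hc.TissueState(np.array([H, S], dtype=np.uint8))
        rng = np.random.default_rng(0)
        s1, log1 = hc.step(state, lat, params, rng)
        assert list(s1.states) == [S, D]
        assert log1 == {"conversions": 1, "deaths": 1, "divisions": 0}
        s2, _ = hc.step(s1, lat, params, rng)
        assert list(s2.states) == [D, D]

    @pytest.mark.parametrize(
        "arr", [np.full(6, H, dtype=np.uint8), np.full(6, D, dtype=np.uint8)]
    )
    def test_absorbing_states_are_fixed_points(self, arr, rng):
        lat = hc.build_chain(6)
        params = hc.Parameters(alpha=1, beta=1, gamma=1, dt=0.25)
        state = hc.TissueState(arr.copy())
        for _ in range(20):
            state, _ = hc.step(state, lat, params, rng)
        assert (state.states == arr).all()

    def test_isolated_vacancy_not_refilled(self, rng):
        # an empty site with no healthy contact neighbor stays empty
        lat = hc.build_chain(4)
        state = hc.TissueState(np.array([D, S, H, H], dtype=np.uint8))
        params = hc.Parameters(alpha=0.25, beta=5, gamma=5, dt=0.25,
                               same_step_vacancies=False)
        nxt, _ = hc.step(state, lat, params, rng)
        assert nxt.states[0] == D


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    geometry=st.sampled_from(["chain", "hex"]),
    seed=st.integers(0, 2**31 - 1),
    alpha=st.floats(0.25, 20),
    beta=st.floats(0.25, 20),
    gamma=st.floats(0.25, 20),
    cap=st.sampled_from([None, 1, 2]),
)
def test_conservation_and_cap_invariants(geometry, seed, alpha, beta, gamma, cap):
    """H + S + D = N after every step; division counters respect the cap."""
    lat = hc.build_chain(6) if geometry == "chain" else hc.build_hex_lobule(2)
    params = hc.Parameters(alpha=alpha, beta=beta, gamma=gamma, dt=0.25, division_cap=cap)
    rng = np.random.default_rng(seed)
    init = hc.init_pericentral(
        lat,
        hc.InitSpec("pericentral_count", stressed_count=3)
        if geometry == "chain"
        else hc.InitSpec("pericentral_layers", stressed_layers=1),
    )
    state = init
    n = lat.n_sites
    for _ in range(40):
        state, _ = hc.step(state, lat, params, rng)
        h, s, d = state.counts()
        assert h + s + d == n
        if cap is not None:
            assert (state.divisions_used <= cap).all()
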