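"""Grid drivers, boundary estimation, phase classification, size scaling."""

import numpy as np
import pytest

import hepatoca as hc
from hepatoca.sweep import SweepGrid


def step_grid(ratios, cols, crossing=2.0, lo=0.5, beta=5.0):
    """Synthetic fixed-beta grid: survival 1 below the crossing, lo above."""
    ratios = np.asarray(ratios, dtype=float)
    survival = np.where(ratios[:, None] > crossing, lo, 1.0) * np.ones((1, len(cols)))
    shape = survival.shape
    full = lambda v: np.full(shape, v)
    return SweepGrid(
        fixed_param="beta", fixed_value=beta,
        row_param="gamma", row_values=ratios * beta,
        col_param="alpha", col_values=np.asarray(cols, dtype=float),
        n_replicas=100, n_sites=10,
        survival=survival,
        n_recovered=(survival * 100).astype(int),
        n_died=((1 - survival) * 100).astype(int),
        n_coexisting=full(0).astype(int),
        mean_divisions=full(2.0),
        mean_min_h_recovered=full(5.0),
        mean_max_h_died=full(6.0),
    )


class TestEstimateCriticalRatio:
    def test_step_function_crossing(self):
        ratios = np.arange(0.1, 4.01, 0.1)
        g = step_grid(ratios, cols=[5, 10, 15], crossing=2.0)
        cr = hc.estimate_critical_ratio(g)
        assert cr.value == pytest.approx(2.1)  # first grid ratio beyond 2.0
        assert cr.sd == 0.0
        assert len(cr.crossings) == 3

    def test_invariant_to_rows_beyond_crossing(self):
        ratios_short = np.arange(0.1, 3.01, 0.1)
        ratios_long = np.arange(0.1, 6.01, 0.1)
        a = hc.estimate_critical_ratio(step_grid(ratios_short, [5, 10]))
        b = hc.estimate_critical_ratio(step_grid(ratios_long, [5, 10]))
        assert a.value == b.value

    def test_offset_columns_excluded(self):
        g = step_grid(np.arange(0.1, 4.01, 0.1), cols=[1, 5, 10])
        cr = hc.estimate_critical_ratio(g, min_offset_columns=1)
        assert set(cr.crossings) == {5.0, 10.0}

    def test_no_crossing_returns_none_with_warning(self):
        g = step_grid(np.arange(0.1, 1.01, 0.1), cols=[5], crossing=5.0)
        with pytest.warns(UserWarning):
            assert hc.estimate_critical_ratio(g) is None


class TestRisingCrossing:
    def test_fixed_gamma_boundary_scans_upward(self):
        """For fixed-gamma sweeps survival *rises* with beta/gamma; the
        boundary is the first scanned ratio reaching ~0.95."""
        betas = np.arange(0.5, 5.01, 0.5)
        survival = np.where(betas[:, None] / 5.0 >= 0.5, 0.99, 0.3) * np.ones((1, 2))
        shape = survival.shape
        g = SweepGrid(
            fixed_param="gamma", fixed_value=5.0,
            row_param="beta", row_values=betas,
            col_param="alpha", col_values=np.array([5.0, 10.0]),
            n_replicas=100, n_sites=10,
            survival=survival,
            n_recovered=(survival * 100).astype(int),
            n_died=((1 - survival) * 100).astype(int),
            n_coexisting=np.zeros(shape, dtype=int),
            mean_divisions=np.full(shape, 1.0),
            mean_min_h_recovered=np.full(shape, 5.0),
            mean_max_h_died=np.full(shape, 6.0),
        )
        cr = hc.estimate_critical_ratio(g, direction="rises_above")
        assert cr.value == pytest.approx(0.5)
        assert cr.sd == 0.0


class TestFitSizeScaling:
    def test_exact_linear_input(self):
        pairs = [(8, 1.6), (16, 3.2), (24, 4.8)]
        slope, se = hc.fit_size_scaling(pairs)
        assert slope == pytest.approx(0.2)
        assert se == pytest.approx(0.0)

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError):
            hc.fit_size_scaling([(8, 1.6), (16, 3.2)])


class TestClassifyPhase:
    def test_labels_and_first_death(self):
        g = step_grid(np.arange(0.5, 3.51, 0.5), cols=[5, 10], crossing=2.0, lo=0.4)
        pm = hc.classify_phase(g)
        assert (pm.labels[g.survival == 1.0] == "S").all()
        assert (pm.labels[g.survival < 1.0] == "SD").all()
        assert pm.first_death_ratio == pytest.approx(2.5)
        assert pm.first_death_sd == 0.0

    def test_pure_recovery_region_label(self):
        g = step_grid(np.arange(0.5, 1.51, 0.5), [5], crossing=10.0)
        pm = hc.classify_phase(g)
        assert (pm.labels == "S").all()
        assert pm.first_death_ratio is None


class TestRunSweep:
    def test_single_point_degenerates_to_ensemble(self, chain10, damage40):
        base = hc.Parameters(5, 5, 5, dt=0.25)
        g = hc.run_sweep(
            chain10, damage40, base, "beta", 5.0,
            "gamma", [0.25], "alpha", [5.0], n_replicas=50, master_seed=4,
            t_max=1000,
        )
        assert g.survival.shape == (1, 1)
        assert g.survival[0, 0] == 1.0  # gamma = dt is certain recovery
        assert g.n_recovered[0, 0] == 50

    def test_axis_below_dt_rejected(self, chain10, damage40):
        base = hc.Parameters(5, 5, 5, dt=0.25)
        with pytest.raises(ValueError):
            hc.run_sweep(
                chain10, damage40, base, "beta", 5.0,
                "gamma", [0.1], "alpha", [5.0], n_replicas=5, master_seed=1,
            )

    def test_reproducible(self, chain10, damage40):
        base = hc.Parameters(5, 5, 5, dt=0.25)
        kw = dict(n_replicas=30, master_seed=77, t_max=800)
        a = hc.run_sweep(chain10, damage40, base, "beta", 5.0,
                         "gamma", [5.25, 10.25], "alpha", [5.0], **kw)
        b = hc.run_sweep(chain10, damage40, base, "beta", 5.0,
                         "gamma", [5.25, 10.25], "alpha", [5.0], **kw)
        assert (a.survival == b.survival).all()
        assert (a.mean_divisions == b.mean_divisions).all()

    def test_long_format_export(self, chain10, damage40):
        base = hc.Parameters(5, 5, 5, dt=0.25)
        g = hc.run_sweep(chain10, damage40, base, "beta", 5.0,
                         "gamma", [0.25, 5.25], "alpha", [5.0, 10.0],
                         n_replicas=10, master_seed=2, t_max=500)
        df = g.to_dataframe()
        assert len(df) == 4
        assert {"survival_probability", "gamma_beta_ratio", "mean_divisions"} <= set(df.columns)


class TestDamageMonotonicity:
    def test_more_initial_damage_never_helps(self, chain10):
        """Survival at matched parameters is lower with more initial
        stressed cells (statistical, 200 replicas per condition)."""
        base = hc.Parameters(5, 5, 12, dt=0.25)
        survs = []
        for s_i in [2, 6]:
            init = hc.init_pericentral(
                chain10, hc.InitSpec("pericentral_count", stressed_count=s_i)
            )
            ens = hc.run_ensemble(chain10, init, base, 200, 99, t_max=4000)
            survs.append(ens.survival_probability)
        assert survs[0] > survs[1]


class TestDivisionCapPhase:
    def test_cap_one_removes_coexistence(self):
        """With one division per cell the 2D coexistence band freezes
        instead; survival is scored as healthy-cells-remaining."""
        lat = hc.build_hex_lobule(6)
        init = hc.init_pericentral(lat, hc.InitSpec("pericentral_layers", stressed_layers=2))
        base = hc.Parameters(5, 5, 5, dt=0.25, division_cap=1)
        g = hc.run_sweep(
            lat, init, base, "beta", 5.0,
            "gamma", [7.25, 12.25, 22.25], "alpha", [5.0],
            n_replicas=10, master_seed=8, t_max=1500,
        )
        pm = hc.classify_phase(g)
        assert not any("C" in lab for lab in pm.labels.ravel())
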