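import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spt_modes import (
    ConfigError,
    ResponseProfile,
    SimulationConfig,
    cell_timestamps,
    response_d_free,
    response_fractions,
    simulate_cell,
    simulate_experiment,
)

PROFILE = ResponseProfile(
    baseline_f_imm=0.105, peak_f_imm=0.295, t_peak=5, decay_tau=10,
    plateau_f_imm=0.17, f_conf=0.281,
)


class TestResponseFractions:
    def test_pre_ligand_returns_baseline(self):
        assert response_fractions(-3.0, PROFILE) == pytest.approx(
            (0.105, 0.281, 1 - 0.105 - 0.281)
        )

    def test_peak_reached_at_t_peak(self):
        f_imm, _, _ = response_fractions(PROFILE.t_peak, PROFILE)
        assert f_imm == pytest.approx(0.295)

    def test_exponential_relaxation_closed_form(self):
        # one decay time past the peak: plateau + (peak - plateau)/e
        f_imm, _, _ = response_fractions(15.0, PROFILE)
        assert f_imm == pytest.approx(0.17 + (0.295 - 0.17) * math.exp(-1), abs=1e-12)

    def test_rejects_non_finite_time(self):
        with pytest.raises(ValueError):
            response_fractions(float("nan"), PROFILE)

    @given(t=st.floats(-10, 40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_fractions_valid_simplex_at_any_time(self, t):
        f = response_fractions(t, PROFILE)
        assert all(0 <= x <= 1 for x in f)
        assert sum(f) == pytest.approx(1.0)

    def test_d_free_dip_lags_immobile_response(self):
        prof = ResponseProfile(D_free_dip_fraction=0.25, t_D_lag=5.0)
        assert response_d_free(-1.0, prof, 0.15) == pytest.approx(0.15)
        assert response_d_free(4.0, prof, 0.15) == pytest.approx(0.15)  # before the lag
        assert response_d_free(7.0, prof, 0.15) < 0.15  # dip underway
        # dip peaks at t_D_lag + t_peak
        t_dip_peak = prof.t_D_lag + prof.t_peak
        assert response_d_free(t_dip_peak, prof, 0.15) == pytest.approx(0.15 * 0.75)


class TestSimulateCell:
    def test_no_motion_no_noise_gives_identical_points(self, rng):
        cfg = SimulationConfig(
            mode_fractions=(0, 0, 1), D_free=0.0, sigma_loc=0.0,
            n_emitters_per_cell=20, n_frames=100,
        )
        table, truth = simulate_cell(cfg, -1.0, rng)
        for eid, g in table.groupby("id"):
            assert g["x"].nunique() == 1 and g["y"].nunique() == 1

    def test_noise_only_mean_squared_step(self, rng):
        # immobile emitters: E[step²] = 4 sigma² (two independent noisy points/axis)
        cfg = SimulationConfig(
            mode_fractions=(1, 0, 0), sigma_loc=0.02,
            n_emitters_per_cell=2000, n_frames=60, p_bleach=0.02,
            staggered_starts=False,
        )
        table, _ = simulate_cell(cfg, -1.0, rng)
        sq = []
        for _, g in table.groupby("id"):
            d = g.sort_values("frame")[["x", "y"]].to_numpy()
            sq.append(((d[1:] - d[:-1]) ** 2).sum(axis=1))
        sq = np.concatenate(sq)
        expected = 4 * 0.02**2
        assert sq.mean() == pytest.approx(expected, rel=3 / math.sqrt(len(sq)) + 0.02)

    def test_brownian_mean_squared_step(self, rng):
        cfg = SimulationConfig(
            mode_fractions=(0, 0, 1), D_free=0.1, sigma_loc=0.0,
            n_emitters_per_cell=2000, n_frames=60, p_bleach=0.02,
            staggered_starts=False,
        )
        table, _ = simulate_cell(cfg, -1.0, rng)
        sq = []
        for _, g in table.groupby("id"):
            d = g.sort_values("frame")[["x", "y"]].to_numpy()
            sq.append(((d[1:] - d[:-1]) ** 2).sum(axis=1))
        sq = np.concatenate(sq)
        assert sq.mean() == pytest.approx(4 * 0.1 * 0.02, rel=0.05)

    def test_free_msd_linear_in_lag(self, rng):
        # lag-n MSD of true positions = 4 D n dt within 3 SE
        d, dt = 0.1, 0.02
        cfg = SimulationConfig(
            mode_fractions=(0, 0, 1), D_free=d, sigma_loc=0.0,
            n_emitters_per_cell=1000, n_frames=10, p_bleach=1e-9,
            staggered_starts=False,
        )
        table, _ = simulate_cell(cfg, -1.0, rng)
        wide = table.pivot_table(index="id", columns="frame", values=["x", "y"])
        for n in range(1, 5):
            dx = wide["x"][n + 0].to_numpy() - wide["x"][0].to_numpy()
            dy = wide["y"][n + 0].to_numpy() - wide["y"][0].to_numpy()
            sq = dx**2 + dy**2
            se = sq.std(ddof=1) / math.sqrt(len(sq))
            assert abs(sq.mean() - 4 * d * n * dt) < 3 * se

    def test_confined_msd_plateaus_below_twice_radius_squared(self, rng):
        r = 0.125
        cfg = SimulationConfig(
            mode_fractions=(0, 1, 0), D_conf=0.1, confinement_radius=r,
            sigma_loc=0.0, n_emitters_per_cell=400, n_frames=200, p_bleach=1e-9,
            staggered_starts=False,
        )
        table, _ = simulate_cell(cfg, -1.0, rng)
        wide = table.pivot_table(index="id", columns="frame", values=["x", "y"])
        lag = 150
        dx = wide["x"][lag].to_numpy() - wide["x"][0].to_numpy()
        dy = wide["y"][lag].to_numpy() - wide["y"][0].to_numpy()
        assert (dx**2 + dy**2).mean() < 2 * r**2

    def test_mode_draw_converges_to_requested_fractions(self, rng):
        cfg = SimulationConfig(
            n_emitters_per_cell=10_000, n_frames=5, p_bleach=0.9,
        )
        _, truth = simulate_cell(cfg, -1.0, rng)
        counts = truth.mode_counts()
        n = sum(counts.values())
        assert n == 10_000
        for mode, f in zip(("immobile", "confined", "free"), cfg.mode_fractions):
            se = math.sqrt(f * (1 - f) / n)
            assert abs(counts[mode] / n - f) < 4 * se

    def test_durations_geometric_mean_one_over_p(self, rng):
        p = 0.064
        cfg = SimulationConfig(
            n_emitters_per_cell=10_000, p_bleach=p, n_frames=1000,
            staggered_starts=False,
        )
        _, truth = simulate_cell(cfg, -1.0, rng)
        durs = np.array([e.n_frames for e in truth.emitters])
        se = durs.std(ddof=1) / math.sqrt(len(durs))
        assert abs(durs.mean() - 1 / p) < 3 * se

    def test_fov_too_small_for_corral_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(fov=(0.2, 0.2), confinement_radius=0.125)


class TestSimulateExperiment:
    def test_sequential_design_five_resting_cells(self):
        cfg = SimulationConfig(n_cells=25, span_min=30, ligand_time=5,
                               n_emitters_per_cell=5, n_frames=50, seed=1)
        t = cell_timestamps(cfg)
        assert len(t) == 25 and np.all(np.diff(t) > 0)
        assert np.sum((t >= -5) & (t < 0)) == 5
        records = simulate_experiment(cfg)
        conditions = [r[2] for r in records]
        assert conditions[:5] == ["resting"] * 5
        assert set(conditions[5:]) == {"stimulated"}

    def test_flat_profile_gives_identical_truth_fractions(self):
        cfg = SimulationConfig(n_cells=25, n_emitters_per_cell=5, n_frames=50, seed=2)
        records = simulate_experiment(cfg)
        fracs = {r[4].fractions for r in records}
        assert len(fracs) == 1

    def test_fixed_seed_reproduces_tables_exactly(self):
        cfg = SimulationConfig(n_cells=3, n_emitters_per_cell=30, n_frames=200, seed=7)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        for (_, _, _, ta, _), (_, _, _, tb, _) in zip(a, b):
            pd.testing.assert_frame_equal(ta, tb)
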