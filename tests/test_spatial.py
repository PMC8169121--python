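"""Spatial maps, I.A.I., reorientation, permutation tests, performance."""

import numpy as np
import pytest

from sniffsearch.spatial import (IAIProfile, SpatialMap, axis_profile,
                                 correct_incorrect_permutation, iai,
                                 iai_axis_profile, occupancy_map,
                                 ranksum_compare, reorient_by_choice,
                                 session_performance, sniff_rate_map,
                                 split_stay_switch, state_occupancy_maps)
from sniffsearch.synthetic import SessionConfig, simulate_session


class TestOccupancyMap:
    def test_point_mass_single_bin(self):
        xy = np.tile([3.3, 7.1], (100, 1))
        m = occupancy_map(xy, bin_size=0.5)
        assert m.grid.shape == (50, 30)
        assert m.grid.sum() == 100
        assert m.grid.max() == 100

    def test_counts_conserved_and_clipping_logged(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform([-1, -1], [26, 16], (1000, 2))
        m = occupancy_map(xy, bin_size=1.0)
        assert m.grid.shape == (25, 15)
        assert m.grid.sum() == 1000          # clipped points kept in edge bins
        assert m.n_clipped > 0

    def test_uniform_points_multinomial_fractions(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform([0, 0], [25, 15], (1_000_000, 2))
        m = occupancy_map(xy, bin_size=0.5, normalize=True)
        p = 1.0 / 1500
        sd = np.sqrt(p * (1 - p) / 1_000_000)
        assert np.abs(m.grid - p).max() < 5 * sd

    def test_misaligned_bins_raise(self):
        with pytest.raises(ValueError):
            occupancy_map(np.zeros((1, 2)), bin_size=0.7)


class TestSniffRateMap:
    def test_one_sniff_per_frame_uniform(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform([0, 0], [25, 15], (5000, 2))
        occ = occupancy_map(xy, bin_size=1.0)
        rate = sniff_rate_map(xy, occ)
        vals = rate.grid[np.isfinite(rate.grid)]
        np.testing.assert_allclose(vals, 1.0)

    def test_no_sniffs_zero_map(self):
        xy = np.tile([5.0, 5.0], (50, 1))
        occ = occupancy_map(xy, bin_size=1.0)
        rate = sniff_rate_map(np.zeros((0, 2)), occ)
        assert np.nansum(rate.grid) == 0.0

    def test_epoch_rates_in_map(self):
        """Sniffs planted at 10 Hz near the port and 5 Hz far from it show
        up as a factor-2 rate ratio."""
        rng = np.random.default_rng(3)
        near = rng.uniform([0, 0], [10, 15], (4000, 2))
        far = rng.uniform([15, 0], [25, 15], (4000, 2))
        frames = np.concatenate([near, far])
        sniff_near = near[rng.random(4000) < 0.125]   # 10 Hz at 80 fps
        sniff_far = far[rng.random(4000) < 0.0625]    # 5 Hz
        occ = occupancy_map(frames, bin_size=1.0)
        rate = sniff_rate_map(np.concatenate([sniff_near, sniff_far]), occ)
        near_mean = np.nanmean(rate.grid[:10])
        far_mean = np.nanmean(rate.grid[15:])
        assert near_mean / far_mean == pytest.approx(2.0, rel=0.15)


class TestStateMapsAndIAI:
    def test_single_state_leaves_other_map_empty(self):
        xy = np.tile([5.0, 5.0], (30, 1))
        inv, app = state_occupancy_maps(xy, np.zeros(30, int))
        assert app.grid.sum() == 0 and inv.grid.sum() == 30

    def test_counts_conserved_across_groups(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform([0, 0], [25, 15], (500, 2))
        lab = rng.integers(-1, 2, 500)
        inv, app = state_occupancy_maps(xy, lab)
        assert inv.grid.sum() + app.grid.sum() == np.sum(lab >= 0)

    @pytest.mark.parametrize("inv_val,app_val,expect", [
        (4.0, 0.0, 1.0), (0.0, 4.0, -1.0), (3.0, 3.0, 0.0)])
    def test_iai_endpoints(self, inv_val, app_val, expect):
        mk = lambda v: SpatialMap(np.full((25, 15), v), 1.0)
        out = iai(mk(inv_val), mk(app_val))
        np.testing.assert_allclose(out.grid, expect)

    def test_iai_antisymmetric(self):
        rng = np.random.default_rng(5)
        a = SpatialMap(rng.random((25, 15)), 1.0)
        b = SpatialMap(rng.random((25, 15)), 1.0)
        np.testing.assert_allclose(iai(a, b).grid, -iai(b, a).grid, atol=1e-12)

    def test_iai_both_zero_missing(self):
        z = SpatialMap(np.zeros((25, 15)), 1.0)
        assert np.isnan(iai(z, z).grid).all()


class TestAxisProfile:
    def test_uniform_map_flat_profile(self):
        m = SpatialMap(np.ones((25, 15)), 1.0)
        p = axis_profile(m, "lateral")
        np.testing.assert_allclose(p.values, 25.0)

    def test_full_zone_equals_unrestricted(self):
        rng = np.random.default_rng(6)
        m = SpatialMap(rng.random((25, 15)), 1.0)
        a = axis_profile(m, "lateral")
        b = axis_profile(m, "lateral", zone=(0.0, 25.0))
        np.testing.assert_allclose(a.values, b.values)

    def test_delta_map_localized(self):
        g = np.zeros((25, 15))
        g[7, 3] = 5.0   # bin centered at (7.5, 3.5)
        m = SpatialMap(g, 1.0)
        p_long = axis_profile(m, "longitudinal")
        assert p_long.values[7] == 5.0 and p_long.values.sum() == 5.0
        p_zone = axis_profile(m, "lateral", zone=(5.0, 10.0))
        assert p_zone.values[3] == 5.0
        p_out = axis_profile(m, "lateral", zone=(10.0, 20.0))
        assert p_out.values.sum() == 0.0

    def test_zone_outside_arena_raises(self):
        m = SpatialMap(np.ones((25, 15)), 1.0)
        with pytest.raises(ValueError):
            axis_profile(m, "lateral", zone=(20.0, 30.0))

    def test_iai_profile_from_projections(self):
        inv = SpatialMap(np.ones((25, 15)), 1.0)
        app = SpatialMap(np.zeros((25, 15)), 1.0)
        p = iai_axis_profile(inv, app, "longitudinal")
        np.testing.assert_allclose(p.values, 1.0)


class TestReorientByChoice:
    def test_all_left_identity(self, small_session):
        bundle, _ = small_session
        left = [t for t in bundle.trials if t.meta.choice == "left"]
        out = reorient_by_choice(left)
        for a, b in zip(left, out):
            np.testing.assert_array_equal(a.nose, b.nose)

    def test_double_application_identity(self, small_session):
        bundle, _ = small_session
        twice = reorient_by_choice(reorient_by_choice(bundle.trials))
        for a, b in zip(bundle.trials, twice):
            np.testing.assert_allclose(b.nose, a.nose, atol=1e-12)

    def test_right_choice_lateral_flip(self, small_session):
        bundle, _ = small_session
        right = [t for t in bundle.trials if t.meta.choice == "right"]
        once = reorient_by_choice(right)
        for a, b in zip(right, once):
            np.testing.assert_allclose(b.nose[:, 1], 15.0 - a.nose[:, 1])
            np.testing.assert_allclose(b.nose[:, 0], a.nose[:, 0])

    def test_reoriented_occupancy_ends_on_one_side(self, small_session):
        bundle, _ = small_session
        out = reorient_by_choice(bundle.trials)
        ends = np.array([t.nose[-1, 1] for t in out])
        assert (ends > 7.5).all()   # every trajectory ends on the high side


class TestCorrectIncorrectPermutation:
    @staticmethod
    def _profiles(n_mice, n_trials, effect, seed):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_mice):
            correct = rng.random(n_trials) < 0.7
            base = rng.normal(0.0, 1.0, (n_trials, 15))
            if effect:
                base[correct, 6:9] += effect
            out.append((base, correct))
        return out

    def test_null_calibrated(self):
        hits = 0
        n_bins = 0
        for rep in range(25):
            data = self._profiles(5, 30, 0.0, seed=rep)
            _, _, p = correct_incorrect_permutation(data, n=200, seed=rep)
            hits += int(np.sum(p < 0.05))
            n_bins += p.shape[0]
        assert hits / n_bins == pytest.approx(0.05, abs=0.04)

    def test_planted_effect_detected_at_affected_bins(self):
        data = self._profiles(6, 40, 1.5, seed=99)
        obs, _, p = correct_incorrect_permutation(data, n=1000, seed=0)
        assert (p[6:9] < 0.01).all()
        assert obs[6:9].mean() > obs[[0, -1]].mean()

    def test_single_class_mouse_excluded(self):
        data = self._profiles(3, 20, 0.0, seed=1)
        allc = (np.zeros((20, 15)), np.ones(20, bool))
        with pytest.warns(UserWarning):
            correct_incorrect_permutation(data + [allc], n=50, seed=2)

    def test_zero_permutations_error(self):
        data = self._profiles(2, 10, 0.0, seed=3)
        with pytest.raises(ValueError):
            correct_incorrect_permutation(data, n=0)


class TestStaySwitch:
    @staticmethod
    def _line_trial(y_path, choice):
        from sniffsearch.session import Trial, TrialMeta
        T = len(y_path)
        x = np.linspace(0.5, 24.5, T)
        nose = np.stack([x, y_path], axis=1)
        meta = TrialMeta(start_s=0.0, end_s=T / 80, side=choice, ratio=(80, 20),
                         choice=choice, correct=True)
        return Trial(nose=nose, head=nose - 0.1, body=nose - 0.2,
                     frame_times=np.arange(T) / 80, sniff=None, trace=None,
                     meta=meta)

    def test_straight_trials_all_stay(self):
        trials = [self._line_trial(np.linspace(7.5, 12.0, 50), "left"),
                  self._line_trial(np.linspace(7.5, 3.0, 50), "right")]
        stay, switch = split_stay_switch(trials)
        assert len(stay) == 2 and len(switch) == 0

    def test_s_shaped_trials_all_switch(self):
        y = np.concatenate([np.linspace(7.5, 11.0, 25), np.linspace(11.0, 3.0, 25)])
        trials = [self._line_trial(y, "right")]
        stay, switch = split_stay_switch(trials)
        assert len(switch) == 1 and len(stay) == 0

    def test_partition_exhaustive_disjoint(self, small_session):
        bundle, _ = small_session
        stay, switch = split_stay_switch(bundle.trials)
        assert len(stay) + len(switch) <= bundle.n_trials
        assert not (set(id(t) for t in stay) & set(id(t) for t in switch))


class TestSessionPerformance:
    def test_all_correct_significant(self):
        cfg = SessionConfig(n_trials=12, always_correct=True, make_traces=False)
        bundle, _ = simulate_session(cfg, seed=1)
        perf = session_performance(bundle.trials)
        assert perf["percent_correct"] == 100.0
        assert perf["binomial_p"] < 0.001
        assert perf["mean_tortuosity"] >= 1.0

    def test_coin_flip_rarely_significant(self):
        from scipy.stats import binomtest
        rng = np.random.default_rng(7)
        n_sig = 0
        for rep in range(40):
            k = int(rng.binomial(200, 0.5))
            p = binomtest(k, 200, 0.5, alternative="greater").pvalue
            n_sig += p < 0.05
        assert n_sig / 40 <= 0.10

    def test_ranksum_helper(self):
        rng = np.random.default_rng(8)
        _, p = ranksum_compare(rng.normal(0, 1, 100), rng.normal(2, 1, 100))
        assert p < 1e-6
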