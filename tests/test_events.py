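import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from naive import naive_detect
from puwarn.events import (
    ClusterResult,
    PeakConfig,
    SmoothingConfig,
    cluster_windows,
    detect_events,
    duration_class,
    extract_windows,
    select_elbow,
    smooth,
    spike_triggered_average,
    sta_by_cluster,
    upsample_sum_load,
    zscore,
)
from puwarn.series import SubjectProfile
from puwarn.simulate import GeneratorConfig, GroupParams, PressureEventSpec, generate_subject


class TestSmooth:
    def test_constant_series_unchanged(self):
        x = np.full(200, 3.7)
        assert np.allclose(smooth(x), x)

    def test_nyquist_alternation_strongly_attenuated(self):
        x = np.array([1.0, -1.0] * 150)
        y = smooth(x)
        # order-2 low-pass at 1/30 cpm: gain at 0.5 cpm is ~0.4%, squared by
        # the forward-backward pass; interior amplitude collapses
        assert np.abs(y[50:-50]).max() < 0.1 * np.abs(x).max()

    def test_white_noise_variance_reduced(self, rng):
        x = rng.normal(0, 1, 500)
        assert smooth(x).var() < x.var()

    def test_short_section_skipped_with_warning(self):
        x = np.arange(4.0)
        with pytest.warns(UserWarning, match="warm-up"):
            y = smooth(x)
        assert np.array_equal(y, x)

    def test_cutoff_must_be_below_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            smooth(np.zeros(100), SmoothingConfig(cutoff=0.6), interval=1)


class TestZscore:
    def test_symmetric_pair(self):
        assert zscore(np.array([0.0, 2.0])).tolist() == [-1.0, 1.0]

    def test_moments(self, rng):
        z = zscore(rng.normal(10, 3, 1000))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    def test_matches_naive_loop(self, rng):
        x = rng.normal(5, 2, 100)
        mean = sum(x) / len(x)
        sd = (sum((v - mean) ** 2 for v in x) / len(x)) ** 0.5
        expected = [(v - mean) / sd for v in x]
        assert np.allclose(zscore(x), expected)

    def test_constant_gives_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            z = zscore(np.full(10, 4.2))
        assert np.array_equal(z, np.zeros(10))


class TestDetectEvents:
    def test_simple_peak(self):
        evs = detect_events(np.array([1.0, 3.0, 1.0]),
                            PeakConfig(min_distance=1, min_prominence=0.5, width_bounds=(0, 10)))
        assert [e.index for e in evs] == [1]
        assert evs[0].direction == "rising"

    def test_plateau_returns_middle(self):
        evs = detect_events(np.array([1.0, 3.0, 3.0, 3.0, 1.0]),
                            PeakConfig(min_distance=1, min_prominence=0.5, width_bounds=(0, 10)))
        assert [e.index for e in evs] == [2]

    def test_even_plateau_lower_middle(self):
        evs = detect_events(np.array([1.0, 3.0, 3.0, 1.0]),
                            PeakConfig(min_distance=1, min_prominence=0.5, width_bounds=(0, 10)))
        assert [e.index for e in evs] == [1]

    def test_monotone_has_no_events(self):
        cfg = PeakConfig(min_distance=1, min_prominence=0.1, width_bounds=(0, 100))
        assert detect_events(np.arange(10.0), cfg) == []
        assert detect_events(-np.arange(10.0), cfg) == []

    def test_falling_events_are_peaks_of_negation(self):
        x = np.array([3.0, 1.0, 3.0])
        cfg = PeakConfig(min_distance=1, min_prominence=0.5, width_bounds=(0, 10))
        evs = detect_events(x, cfg, direction="falling")
        assert [e.index for e in evs] == [1]
        assert evs[0].direction == "falling"

    def test_short_series_empty(self):
        assert detect_events(np.array([1.0, 2.0])) == []

    def test_min_distance_keeps_higher_prominence(self):
        # two nearby peaks, the second more prominent
        x = np.array([0.0, 2.0, 1.0, 3.0, 0.0])
        cfg = PeakConfig(min_distance=4, min_prominence=0.5, width_bounds=(0, 10))
        evs = detect_events(x, cfg)
        assert [e.index for e in evs] == [3]

    def test_t_grid_maps_to_minutes(self):
        x = np.array([0.0, 2.0, 0.0])
        t = np.array([100, 105, 110])
        cfg = PeakConfig(min_distance=5, min_prominence=0.5, width_bounds=(0, 100))
        evs = detect_events(x, cfg, t=t, interval=5)
        assert evs[0].t_peak == 105

    @settings(max_examples=200, deadline=None)
    @given(series=st.lists(st.sampled_from([0.0, 1.0, 2.0, 3.0]), min_size=3, max_size=30))
    def test_equivalent_to_bruteforce_on_random_series(self, series):
        cfg = PeakConfig(min_distance=3, min_prominence=1.0, width_bounds=(1.0, 8.0))
        got = [(e.index, e.prominence, e.width) for e in detect_events(np.array(series), cfg)]
        expected = naive_detect(series, 3, 1.0, 1.0, 8.0)
        assert [g[0] for g in got] == [e[0] for e in expected]
        for g, e in zip(got, expected):
            assert g[1] == pytest.approx(e[1], abs=1e-12)
            assert g[2] == pytest.approx(e[2], abs=1e-12)


def _detected_windows(config, direction="rising"):
    profile = SubjectProfile(subject_id="S", group="patient")
    vitals, pressure = generate_subject(profile, config)
    t, load = upsample_sum_load(pressure, 1)
    z = zscore(smooth(load))
    events = detect_events(z, direction=direction, t=t)
    temp = np.where(vitals.temp_valid, vitals.temp, np.nan)
    n = min(t.size, vitals.n)
    return events, extract_windows(events, t[:n], z[:n], temp[:n])


class TestExtractWindows:
    def test_window_bounds(self):
        t = np.arange(200)
        x = np.zeros(200)
        temp = np.full(200, 36.0)
        from puwarn.events import PressureEvent

        ev = PressureEvent(t_peak=100, index=100, direction="rising", prominence=2.0, width=20.0)
        wins = extract_windows([ev], t, x, temp)
        assert len(wins) == 1
        w = wins[0]
        assert w.rel_time[0] == -5 and w.rel_time[-1] == 55 and w.rel_time.size == 61
        assert np.array_equal(w.pressure_traj, x[95:156])

    def test_boundary_event_excluded(self):
        from puwarn.events import PressureEvent

        t = np.arange(100)
        ev = PressureEvent(t_peak=3, index=3, direction="rising", prominence=2.0, width=20.0)
        assert extract_windows([ev], t, np.zeros(100), np.full(100, 36.0)) == []

    def test_temperature_gap_disqualifies(self):
        from puwarn.events import PressureEvent

        t = np.arange(200)
        temp = np.full(200, 36.0)
        temp[120] = np.nan
        ev = PressureEvent(t_peak=100, index=100, direction="rising", prominence=2.0, width=20.0)
        assert extract_windows([ev], t, np.zeros(200), temp) == []

    def test_count_equals_events_minus_exclusions(self, event_config):
        events, windows = _detected_windows(event_config)
        excluded = sum(
            1 for e in events if e.t_peak - 5 < 0 or e.t_peak + 55 >= event_config.duration
        )
        assert len(windows) == len(events) - excluded


class TestClusterWindows:
    def test_k1_center_is_mean_of_scaled_trajectories(self, event_config):
        _, windows = _detected_windows(event_config)
        assert len(windows) >= 2
        result = cluster_windows(windows, k_candidates=[1], seed=0)
        scaled = np.vstack(
            [(w.pressure_traj - w.pressure_traj.mean()) / w.pressure_traj.std() for w in windows]
        )
        assert np.allclose(result.centers[0], scaled.mean(axis=0), atol=1e-8)

    def test_duration_recovery_two_classes(self):
        cfg = GeneratorConfig(
            duration=8000,
            seed=17,
            pressure_noise_sd=0.01,
            pressure_events=tuple(
                PressureEventSpec(start=s, duration=(20 if i % 2 == 0 else 40), amplitude=5.0)
                for i, s in enumerate(range(200, 7800, 400))
            ),
        )
        events, windows = _detected_windows(cfg)
        assert len(windows) >= 10
        result = cluster_windows(windows, k_candidates=[2], seed=0)
        # map each window back to its scheduled duration
        scheduled = {s: (20 if i % 2 == 0 else 40) for i, s in enumerate(range(200, 7800, 400))}
        true_dur = []
        for w in windows:
            nearest = min(scheduled, key=lambda s: abs(w.event.t_peak - (s + scheduled[s] / 2)))
            true_dur.append(scheduled[nearest])
        true_dur = np.array(true_dur)
        for label in (0, 1):
            durs = true_dur[result.labels == label]
            assert len(set(durs.tolist())) == 1  # pure clusters

    def test_inertia_non_increasing_in_k(self, event_config):
        _, windows = _detected_windows(event_config)
        ks = [k for k in (1, 2, 3) if k <= len(windows)]
        result = cluster_windows(windows, k_candidates=ks, seed=0)
        inertias = [result.inertia_by_k[k] for k in sorted(result.inertia_by_k)]
        assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_fixed_seed_reproducible(self, event_config):
        _, windows = _detected_windows(event_config)
        r1 = cluster_windows(windows, k_candidates=[2], seed=5)
        r2 = cluster_windows(windows, k_candidates=[2], seed=5)
        assert np.array_equal(r1.labels, r2.labels)

    def test_oversized_k_skipped_with_warning(self, event_config):
        _, windows = _detected_windows(event_config)
        with pytest.warns(UserWarning, match="skipping"):
            result = cluster_windows(windows, k_candidates=[1, len(windows) + 5], seed=0)
        assert result.k == 1

    def test_empty_windows_rejected(self):
        with pytest.raises(ValueError, match="no windows"):
            cluster_windows([], k_candidates=[1])


class TestElbow:
    def test_clear_elbow(self):
        inertia = {1: 100.0, 2: 20.0, 3: 15.0, 4: 12.0}
        assert select_elbow(inertia) == 2

    def test_two_candidates_pick_largest(self):
        assert select_elbow({2: 50.0, 3: 10.0}) == 3

    def test_duration_class_bins(self):
        assert duration_class(18.0) == "20"
        assert duration_class(42.0) == "40"
        assert duration_class(70.0) == ">55"


class TestSTA:
    def _const_window(self, temp_value=36.0, rel=None):
        from puwarn.events import EventWindow, PressureEvent

        rel = np.arange(-5, 56) if rel is None else rel
        ev = PressureEvent(t_peak=0, index=0, direction="rising", prominence=2.0, width=20.0)
        return EventWindow(
            event=ev,
            rel_time=rel.copy(),
            pressure_traj=np.linspace(0, 1, rel.size),
            temp_traj=np.full(rel.size, temp_value),
        )

    def test_constant_windows_give_zero_sta_and_absent_correlations(self):
        entry = spike_triggered_average([self._const_window(), self._const_window(35.0)],
                                        pressure_center=np.linspace(0, 1, 61))
        assert np.array_equal(entry.mean_delta_temp, np.zeros(61))
        assert entry.pearson_r is None and entry.spearman_rho is None

    def test_single_window_is_its_relative_trajectory(self, rng):
        w = self._const_window()
        w.temp_traj = rng.normal(36, 0.5, 61)
        entry = spike_triggered_average([w])
        ref = w.temp_traj[4]  # rel_time -1
        assert np.allclose(entry.mean_delta_temp, w.temp_traj - ref)
        assert entry.mean_delta_temp[4] == 0.0

    def test_zero_at_reference_always(self, rng):
        wins = []
        for _ in range(7):
            w = self._const_window()
            w.temp_traj = rng.normal(36, 0.5, 61)
            wins.append(w)
        entry = spike_triggered_average(wins)
        assert entry.mean_delta_temp[4] == 0.0

    @staticmethod
    def _step_response(gain, lag=5.0):
        # lasting load arriving at rel 0; first-order lagged response
        rel = np.arange(-5, 56)
        step = (rel >= 0).astype(float)
        alpha = 1 - np.exp(-1 / lag)
        lagged = np.zeros(rel.size)
        for i in range(1, rel.size):
            lagged[i] = lagged[i - 1] + alpha * (step[i] - lagged[i - 1])
        return rel, step, gain * lagged

    def test_coupled_windows_recover_gain(self):
        g = 0.5
        rel, step, response = self._step_response(g)
        wins = []
        for _ in range(5):
            w = self._const_window()
            w.pressure_traj = step.copy()
            w.temp_traj = 36.0 + response
            wins.append(w)
        # score against the closed-form lagged response of the center
        entry = spike_triggered_average(wins, pressure_center=response / g)
        assert entry.pearson_r is not None and entry.pearson_r > 0.9
        assert np.allclose(entry.mean_delta_temp, response, atol=1e-12)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            spike_triggered_average([])

    def test_sign_consistency_with_positive_coupling(self):
        # rising lasting load -> STA increasing after t=0; falling -> decreasing
        g = 0.5
        rel, step, response = self._step_response(g)
        rising, falling = [], []
        for _ in range(5):
            w = self._const_window()
            w.pressure_traj = step.copy()
            w.temp_traj = 36.0 + response
            rising.append(w)
            w2 = self._const_window()
            w2.event.direction = "falling"
            w2.pressure_traj = 1.0 - step
            w2.temp_traj = 36.0 - response
            falling.append(w2)
        up = spike_triggered_average(rising).mean_delta_temp
        down = spike_triggered_average(falling).mean_delta_temp
        after = rel >= 0
        assert np.all(np.diff(up[after]) > 0)
        assert np.all(np.diff(down[after]) < 0)

    def test_pipeline_sta_tracks_pressure_center(self):
        cfg = GeneratorConfig(
            duration=6000,
            seed=23,
            pressure_noise_sd=0.01,
            temp_coupling_gain=0.5,
            temp_coupling_lag=5.0,
            group_params={"patient": GroupParams(91.3, 0.0, 70.2, 0.0, 36.0, 0.0)},
            pressure_events=tuple(
                PressureEventSpec(start=s, duration=30, amplitude=5.0)
                for s in range(300, 5700, 400)
            ),
        )
        events, windows = _detected_windows(cfg, direction="rising")
        assert windows
        result = cluster_windows(windows, k_candidates=[1], seed=0)
        entry = sta_by_cluster(windows, result)[0]
        # the temperature average follows the pressure center's shape
        assert entry.pearson_r is not None and entry.pearson_r > 0.3
        assert entry.mean_delta_temp[4] == 0.0
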