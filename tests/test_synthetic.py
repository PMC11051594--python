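"""Synthetic-experiment generator: state switching, whistle trains, ping
schedules, response injection, tracks and full bundles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from whistlecee.geometry import haversine_distance, interpolate_positions
from whistlecee.synthetic import (
    SimConfig,
    inject_ping_response,
    make_ping_schedule,
    simulate_cee,
    simulate_tracks,
    simulate_vocal_states,
    simulate_whistle_train,
    write_cee_bundle,
)


class TestVocalStates:
    def test_zero_rate_constant_sequence(self):
        cfg = SimConfig(n_states=1, state_intensities=(2.0,), mean_switch_rate=0.0)
        states = simulate_vocal_states(cfg, "mean")
        assert (states == states[0]).all()

    @pytest.mark.parametrize(
        "rate,expected", [(1.0, 30.0), (1.0 / 3.5, 30.0 / 3.5)]
    )
    def test_monte_carlo_switch_count(self, rate, expected):
        """The number of switching events over 30 min is Poisson with mean
        rate x 30; the Monte-Carlo mean over 10,000 replicates must sit
        within 3 standard errors."""
        reps = 10_000
        counts = np.empty(reps)
        rng = np.random.default_rng(42)
        cfg = SimConfig(mean_switch_rate=rate)
        for i in range(reps):
            _, times = simulate_vocal_states(cfg, "mean", rng=rng, return_times=True)
            counts[i] = times.size
        se = np.sqrt(expected / reps)
        assert abs(counts.mean() - expected) <= 3 * se

    def test_reproducible_given_seed(self):
        cfg = SimConfig(seed=5)
        a = simulate_vocal_states(cfg, "mean")
        b = simulate_vocal_states(cfg, "mean")
        assert np.array_equal(a, b)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(duration_s=0, phase_bounds=(0,))


class TestWhistleTrain:
    def test_silent_group(self):
        cfg = SimConfig(state_intensities=(0.0, 0.0))
        counts, det = simulate_whistle_train(np.zeros(1800, int), cfg)
        assert counts.sum() == 0 and len(det) == 0

    def test_single_state_mean(self):
        cfg = SimConfig(
            n_states=1, state_intensities=(3.0,), mean_switch_rate=0.0,
            duration_s=100_000, phase_bounds=(0, 30_000, 60_000, 100_000), seed=2,
        )
        counts, _ = simulate_whistle_train(np.zeros(100_000, int), cfg)
        se = np.sqrt(3.0 / 100_000)
        assert abs(counts.mean() - 3.0) <= 3 * se

    def test_per_state_conditional_means(self):
        cfg = SimConfig(state_intensities=(0.3, 4.6), seed=3,
                        duration_s=20_000, phase_bounds=(0, 5000, 10_000, 20_000))
        states = (np.arange(20_000) // 100) % 2
        counts, det = simulate_whistle_train(states, cfg)
        for s, lam in [(0, 0.3), (1, 4.6)]:
            vals = counts[states == s]
            se = np.sqrt(lam / vals.size)
            assert abs(vals.mean() - lam) <= 3 * se
        # conservation: detections equal the summed counts
        assert len(det) == counts.sum()

    def test_detection_starts_within_their_second(self, control_cee):
        det = control_cee.detections
        sub = det[det.buoy_id == "buoy_1"]
        counts = np.bincount(sub.start_s.astype(int), minlength=1800)
        assert np.array_equal(counts, control_cee.counts.counts)


class TestPingSchedule:
    def test_study_schedule(self):
        s = make_ping_schedule(600.0, 24, 25.0, 1.6, phase_end_s=1200.0)
        assert s.onsets_s[0] == 600.0 and s.onsets_s[-1] == 1175.0
        assert np.allclose(np.diff(s.onsets_s), 25.0)
        assert s.onsets_s[-1] + s.duration_s == pytest.approx(1176.6)

    def test_single_ping(self):
        s = make_ping_schedule(600.0, 1, 25.0, 1.6)
        assert list(s.onsets_s) == [600.0]

    def test_duration_exceeding_interval_rejected(self):
        with pytest.raises(ValueError, match="shorter than the interval"):
            make_ping_schedule(600.0, 24, 25.0, 26.0)

    def test_phase_overrun_rejected(self):
        with pytest.raises(ValueError, match="overruns"):
            make_ping_schedule(600.0, 25, 25.0, 1.6, phase_end_s=1200.0)


def response_profile(t_after_end, cfg):
    """Independent statement of the injected intensity multiplier as a
    function of time since the transmission ended."""
    if t_after_end < cfg.response_duration_s:
        return cfg.response_fold
    tau = cfg.response_decay_s / 3.0
    return 1.0 + (cfg.response_fold - 1.0) * np.exp(-(t_after_end - cfg.response_duration_s) / tau)


class TestInjection:
    def _cfg(self, **kw):
        return SimConfig(cee_type="mfas", **kw)

    def test_null_response_identity(self):
        cfg = self._cfg(response_fold=1.0, suppress_during_ping=False, seed=1)
        counts = np.random.default_rng(0).poisson(2.0, 1800)
        sched = make_ping_schedule(600.0, 24, 25.0, 1.6, phase_end_s=1200.0)
        out, _ = inject_ping_response(counts, sched, cfg, np.full(1800, 2.0))
        assert np.array_equal(out, counts)

    def test_suppression_zeroes_transmission_seconds(self):
        cfg = self._cfg(response_fold=1.0, suppress_during_ping=True, seed=1)
        counts = np.full(1800, 5)
        sched = make_ping_schedule(600.0, 24, 25.0, 1.6, phase_end_s=1200.0)
        out, _ = inject_ping_response(counts, sched, cfg, np.full(1800, 5.0))
        for onset in sched.onsets_s:
            assert out[int(onset)] == 0 and out[int(onset) + 1] == 0

    def test_overlapping_response_windows_rejected(self):
        cfg = self._cfg(response_fold=4.0, response_duration_s=30.0)
        counts = np.zeros(1800, int)
        sched = make_ping_schedule(600.0, 2, 25.0, 1.6, phase_end_s=1200.0)
        with pytest.raises(ValueError, match="overlap"):
            inject_ping_response(counts, sched, cfg, np.ones(1800))

    def test_mean_burst_matches_numerical_integration(self):
        """MC mean of post-ping counts agrees with numerical integration of
        the stated decay profile (15-fold burst on a 1 whistle/s baseline,
        10,000 replicate pings)."""
        cfg = self._cfg(response_fold=15.0, suppress_during_ping=True, seed=123)
        n_pings, reps = 500, 20
        length = int(25.0 * n_pings + 100)
        sched = make_ping_schedule(0.0, n_pings, 25.0, 1.6, phase_end_s=length)
        rng = np.random.default_rng(99)
        intensity = np.ones(length)
        # bins 2..6 lie fully inside [1.6, 6.6) + decay seconds onward
        per_ping_bins = np.arange(2, 7)
        totals = []
        for _ in range(reps):
            base = rng.poisson(1.0, length)
            out, _ = inject_ping_response(base, sched, cfg, intensity, rng=rng)
            for onset in sched.onsets_s.astype(int):
                totals.append(out[onset + per_ping_bins].sum())
        totals = np.asarray(totals, dtype=float)
        expected = sum(
            integrate.quad(lambda t: response_profile(t - 1.6, cfg), k, k + 1)[0]
            for k in per_ping_bins
        )
        se = np.sqrt(expected / totals.size)
        assert abs(totals.mean() - expected) <= 3 * se


class TestTracks:
    def test_zero_speed_stationary(self):
        cfg = SimConfig(group_speed_mps=0.0, buoy_speed_mps=0.0, seed=4)
        tracks = simulate_tracks(cfg)
        for tr in tracks:
            assert np.ptp(tr.lat_deg) == 0.0 and np.ptp(tr.lon_deg) == 0.0

    def test_one_fix_per_minute_inclusive(self):
        tracks = simulate_tracks(SimConfig(seed=4))
        assert all(len(tr) == 31 for tr in tracks)

    def test_crossing_scenario_crosses_threshold(self):
        cfg = SimConfig(track_scenario="crossing", seed=6)
        tracks = simulate_tracks(cfg)
        group, crossing_buoy = tracks[0], tracks[-1]
        dists = [
            haversine_distance(
                (group.lat_deg[i], group.lon_deg[i]),
                (crossing_buoy.lat_deg[i], crossing_buoy.lon_deg[i]),
            )
            for i in range(len(group))
        ]
        assert min(dists) < 1600 < max(dists)


class TestFullBundle:
    def test_control_truth_has_no_response_windows(self, control_cee):
        assert control_cee.truth["response_windows"] == []
        assert control_cee.schedule.is_pseudo

    def test_mfas_truth_lists_all_response_windows(self, mfas_cee):
        assert len(mfas_cee.truth["response_windows"]) == 24
        assert not mfas_cee.schedule.is_pseudo

    def test_truth_state_sequence_covers_duration(self, control_cee):
        assert len(control_cee.truth["states"]) == control_cee.config.duration_s

    def test_serialized_bundle_is_byte_identical(self, tmp_path):
        cfg = SimConfig(cee_id="repro", cee_type="mfas", response_fold=4.0,
                        suppress_during_ping=True, rl_max_db=150.0, seed=21)
        p1 = write_cee_bundle(simulate_cee(cfg), tmp_path / "a")
        p2 = write_cee_bundle(simulate_cee(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_null_mfas_indistinguishable_from_control(self):
        """With no injected response, sonar and control simulations draw
        from the same count process.  Per-second counts are serially
        dependent within a realization, so the comparison is made on
        independent replicate-level statistics: 100 + 100 replicate mean
        counts (and exposure-phase means), tested at alpha = 0.01 with
        Bonferroni control over the two tests."""
        mfas_means, ctl_means, mfas_exp, ctl_exp = [], [], [], []
        for seed in range(100):
            m = simulate_cee(SimConfig(cee_id="m", cee_type="mfas",
                                       response_fold=1.0, seed=seed))
            c = simulate_cee(SimConfig(cee_id="c", cee_type="control",
                                       seed=seed + 10_000))
            mfas_means.append(m.counts.counts.mean())
            ctl_means.append(c.counts.counts.mean())
            mfas_exp.append(m.counts.masked_values("exposure").mean())
            ctl_exp.append(c.counts.masked_values("exposure").mean())
        p1 = stats.mannwhitneyu(mfas_means, ctl_means).pvalue
        p2 = stats.mannwhitneyu(mfas_exp, ctl_exp).pvalue
        assert min(p1, p2) > 0.01 / 2

    def test_count_conservation(self, mfas_cee):
        per_buoy = mfas_cee.detections.groupby("buoy_id").size()
        assert (per_buoy == mfas_cee.counts.counts.sum()).all()
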