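"""Generator properties: determinism, label structure, spectra, detector quality."""

import numpy as np
import pytest
from scipy.signal import periodogram
from scipy.stats import spearmanr

from fogbench.core_io import Dialect
from fogbench.errors import ValidationError
from fogbench.scoring import average_precision
from fogbench.synthetic import (REST, TURN, WALK, SimConfig, _simulate_states,
                                cohort_manifest, default_hourly_intensity,
                                generate_protocol_session, generate_week,
                                simulate_detector, subject_propensity,
                                synthesize_signal, _rng)


def small_cfg(**kw):
    kw.setdefault("seed", 11)
    kw.setdefault("session_duration_s", 120)
    kw.setdefault("synthesize_acc", False)
    return SimConfig(**kw)


class TestProtocolSessions:
    def test_zero_triggers_zero_fog(self):
        cfg = small_cfg(fog_trigger_probs={"turn": 0.0, "walk": 0.0,
                                           "gait_initiation": 0.0})
        _, labels = generate_protocol_session(cfg)
        assert not labels.any_fog.any()

    def test_deterministic_given_seed(self):
        cfg = small_cfg(synthesize_acc=True)
        rec1, lab1 = generate_protocol_session(cfg)
        rec2, lab2 = generate_protocol_session(cfg)
        np.testing.assert_array_equal(rec1.acc, rec2.acc)
        np.testing.assert_array_equal(lab1.any_fog, lab2.any_fog)

    def test_different_sessions_differ(self):
        cfg = small_cfg()
        _, a = generate_protocol_session(cfg, session_id="t1")
        _, b = generate_protocol_session(cfg, session_id="t2")
        assert not np.array_equal(a.turn, b.turn)

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            generate_protocol_session(small_cfg(session_duration_s=0))

    def test_labels_mutually_exclusive(self):
        cfg = small_cfg(session_duration_s=600, notype_fraction=0.2)
        _, labels = generate_protocol_session(cfg)
        stacked = (labels.start_hesitation.astype(int) + labels.turn
                   + labels.walking + labels.notype)
        assert stacked.max() <= 1

    def test_class_shares_track_trigger_configuration(self):
        # aggregate episode counts over many sessions; turn-heavy triggers
        # must yield turn as the dominant class, walking next
        from fogbench.episodes import extract_episodes
        cfg = small_cfg(session_duration_s=300,
                        fog_trigger_probs={"turn": 0.6, "walk": 0.15,
                                           "gait_initiation": 0.05})
        counts = {"turn": 0, "walking": 0, "start_hesitation": 0}
        for i in range(60):
            _, labels = generate_protocol_session(cfg, session_id=f"s{i}")
            for cls in counts:
                counts[cls] += len(extract_episodes(
                    labels.class_channel(cls), cfg.sampling_rate))
        total = sum(counts.values())
        assert total > 50
        assert counts["turn"] > counts["walking"] > counts["start_hesitation"]
        assert counts["turn"] / total > 0.5


class TestSignal:
    def test_walking_spectral_peak_at_step_frequency(self):
        cfg = SimConfig(seed=3, sampling_rate=128.0)
        n = 30 * 128
        states = np.full(n, WALK, dtype=np.int8)
        fog = np.full(n, -1, dtype=np.int8)
        acc = synthesize_signal(states, fog, np.zeros(n, bool), cfg)
        f, pxx = periodogram(acc[:, 0] - acc[:, 0].mean(), fs=128.0)
        assert f[np.argmax(pxx)] == pytest.approx(cfg.walk_step_freq, abs=0.2)

    def test_akinetic_variance_far_below_walking(self):
        cfg = SimConfig(seed=4, sampling_rate=128.0)
        n = 20 * 128
        walk = synthesize_signal(np.full(n, WALK, np.int8),
                                 np.full(n, -1, np.int8), np.zeros(n, bool), cfg)
        akin = synthesize_signal(np.full(n, WALK, np.int8),
                                 np.ones(n, np.int8), np.ones(n, bool), cfg)
        assert akin[:, 0].var() < 0.1 * walk[:, 0].var()

    def test_noiseless_rest_is_constant(self):
        cfg = SimConfig(seed=5, sampling_rate=128.0, noise_sd=0.0)
        n = 256
        acc = synthesize_signal(np.full(n, REST, np.int8),
                                np.full(n, -1, np.int8), np.zeros(n, bool), cfg)
        assert np.ptp(acc[:, 0]) == pytest.approx(0.0, abs=1e-9)

    def test_trembling_power_concentrated_in_freeze_band(self):
        cfg = SimConfig(seed=6, sampling_rate=128.0, noise_sd=0.01)
        n = 30 * 128
        acc = synthesize_signal(np.full(n, WALK, np.int8), np.ones(n, np.int8),
                                np.zeros(n, bool), cfg)
        f, pxx = periodogram(acc[:, 0] - acc[:, 0].mean(), fs=128.0)
        band = (f >= 3) & (f <= 8)
        assert pxx[band].sum() / pxx.sum() > 0.9


class TestWeek:
    def test_non_freezer_has_zero_fog(self):
        cfg = SimConfig(seed=8, dialect=Dialect.daily, sampling_rate=0.5,
                        group="non_freezer", synthesize_acc=False)
        _, labels, _ = generate_week(cfg, "N000")
        assert not labels.any_fog.any()

    def test_fog_only_within_bouts(self):
        cfg = SimConfig(seed=9, dialect=Dialect.daily, sampling_rate=0.5,
                        synthesize_acc=False)
        _, labels, bouts = generate_week(cfg, "F000")
        membership = bouts.membership(len(labels))
        assert not (labels.any_fog & ~membership).any()

    def test_seven_days_exactly(self):
        cfg = SimConfig(seed=10, dialect=Dialect.daily, sampling_rate=0.5,
                        synthesize_acc=False)
        rec, _, _ = generate_week(cfg, "F000")
        assert rec.n_samples == int(7 * 86400 * 0.5)

    def test_peak_hours_recovered_in_cohort_mean(self):
        from fogbench.daily import expand_bouts, hourly_tf
        cfg = SimConfig(seed=21, dialect=Dialect.daily, sampling_rate=0.5,
                        synthesize_acc=False,
                        hourly_intensity=default_hourly_intensity(night=0.0))
        curves = []
        for i in range(20):
            rec, labels, bouts = generate_week(cfg, f"F{i:03d}")
            bm = expand_bouts(bouts, 5.0, rec.n_samples, cfg.sampling_rate)
            _, wk = hourly_tf(labels.any_fog, bm, rec.start_clock,
                              cfg.sampling_rate)
            curves.append(wk)
        mean_curve = np.nanmean(np.vstack(curves), axis=0)
        top2 = set(np.argsort(np.nan_to_num(mean_curve))[-2:].tolist())
        assert any(abs(h - 7) <= 1 for h in top2)
        assert any(abs(h - 22) <= 1 for h in top2)


class TestSimulateDetector:
    def test_high_quality_perfect_ranking(self):
        cfg = small_cfg(session_duration_s=240)
        _, labels = generate_protocol_session(cfg)
        scores = simulate_detector(labels, 50.0, seed=1,
                                   sampling_rate=cfg.sampling_rate)
        assert labels.turn.any()
        assert average_precision(labels.turn, scores.turn) == 1.0

    def test_zero_quality_ap_near_prevalence(self, rng):
        prevs, aps = [], []
        for rep in range(50):
            labels_arr = rng.random(500) < 0.15
            if not labels_arr.any():
                continue
            from conftest import make_labels
            labels = make_labels(turn=labels_arr)
            scores = simulate_detector(labels, 0.0, seed=rep, sampling_rate=100)
            prevs.append(labels_arr.mean())
            aps.append(average_precision(labels_arr, scores.turn))
        assert np.mean(aps) == pytest.approx(np.mean(prevs), abs=0.03)

    def test_ap_monotone_in_quality(self):
        cfg = small_cfg(session_duration_s=240)
        _, labels = generate_protocol_session(cfg)
        qualities = np.linspace(0, 5, 20)
        aps = [average_precision(
            labels.any_fog,
            simulate_detector(labels, q, seed=7 + i, sampling_rate=128).max_over_classes)
            for i, q in enumerate(qualities)]
        rho, _ = spearmanr(qualities, aps)
        assert rho > 0.9

    def test_negative_quality_rejected(self):
        from conftest import make_labels
        with pytest.raises(ValidationError):
            simulate_detector(make_labels(n=4), -1.0)

    def test_deterministic(self):
        from conftest import make_labels
        labels = make_labels(turn=[0, 1, 1, 0, 0])
        a = simulate_detector(labels, 2.0, seed=5)
        b = simulate_detector(labels, 2.0, seed=5)
        np.testing.assert_array_equal(a.as_matrix(), b.as_matrix())


class TestCohort:
    def test_manifest_scores_track_propensity(self):
        cfg = SimConfig(seed=13, dialect=Dialect.daily, synthesize_acc=False)
        manifest = cohort_manifest(cfg, 45, 19)
        assert len(manifest) == 64
        freezers = manifest[manifest.group == "freezer"]
        props = [subject_propensity(cfg, s) for s in freezers.subject_id]
        rho, _ = spearmanr(props, freezers.nfogq)
        assert rho > 0.9
        assert (manifest[manifest.group == "non_freezer"].nfogq == 0).all()
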