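"""Synthetic pulse-wave generator: template shape, construction identities,
dataset bookkeeping and reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pulsesite as ps
from pulsesite.synthdata import ARTERY_CLASSES, _SITE_DEFAULTS


class TestPulseTemplate:
    def test_zero_amplitude_gives_zero_segment(self):
        seg = ps.pulse_template(ps.Morphology(), 1000, 0.0)
        assert np.all(seg == 0.0) and len(seg) == 1000

    def test_peak_to_trough_equals_programmed_amplitude(self):
        # programmed with the posterior-tibial mean pulse amplitude
        seg = ps.pulse_template(ps.Morphology(), 1200, 0.304)
        assert seg.max() - seg.min() == pytest.approx(0.304, rel=1e-9)

    def test_systolic_peak_sits_at_midpoint(self):
        seg = ps.pulse_template(ps.Morphology(), 1001, 1.0)
        assert seg.argmax() == 1001 // 2

    def test_no_notch_means_single_local_maximum(self):
        m = ps.Morphology(notch_amp_frac=0.0, reflected_amp_frac=0.5)
        seg = ps.pulse_template(m, 900, 1.0)
        interior = (seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:])
        assert interior.sum() == 1

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            ps.pulse_template(ps.Morphology(), 4, 1.0)
        with pytest.raises(ValueError):
            ps.pulse_template(ps.Morphology(), 100, -0.1)

    @settings(derandomize=True, max_examples=30)
    @given(amp=st.floats(1e-3, 20.0),
           n=st.integers(50, 2000),
           ws=st.floats(0.05, 0.4), nd=st.floats(0.1, 0.6),
           na=st.floats(0.0, 0.8), ra=st.floats(0.0, 0.8))
    def test_template_contract_holds_across_morphologies(self, amp, n, ws,
                                                         nd, na, ra):
        m = ps.Morphology(ws, min(nd, 1.0), na, ra)
        seg = ps.pulse_template(m, n, amp)
        assert len(seg) == n
        assert seg.argmax() == n // 2
        assert seg.max() - seg.min() == pytest.approx(amp, rel=1e-9)
        assert seg.min() == 0.0


class TestGenerateRecording:
    def test_sixty_bpm_sixty_seconds_gives_sixty_beats(self):
        cfg = ps.default_config("C", heart_rate_mean=60.0, heart_rate_sd=0.0)
        rec = ps.generate_recording(cfg)
        assert len(rec.beat_indices) == 60

    def test_flat_configuration_yields_constant_baseline(self):
        cfg = ps.default_config("C", delta_z_amp=0.0, drift_amp=0.0,
                                noise_sd=0.0)
        rec = ps.generate_recording(cfg)
        assert np.allclose(rec.channels["z_100k"], cfg.z0, atol=1e-12)

    def test_jitter_free_signal_is_periodic_at_the_cardiac_period(self,
                                                                  clean_config):
        rec = ps.generate_recording(clean_config)
        x = rec.channels["z_100k"] - rec.channels["z_100k"].mean()
        n = len(x)
        ac = np.fft.irfft(np.abs(np.fft.rfft(x)) ** 2, n)
        expected_lag = int(round(clean_config.fs * 60.0
                                 / clean_config.heart_rate_mean))
        lo, hi = int(0.6 * expected_lag), int(1.5 * expected_lag)
        assert lo + ac[lo:hi].argmax() == pytest.approx(expected_lag, abs=1)

    def test_construction_identity_recovers_pulse_train(self, clean_config):
        rec, comp = ps.generate_recording(clean_config,
                                          return_components=True)
        for ch, (base_drift, pulse) in comp.items():
            np.testing.assert_allclose(rec.channels[ch] - base_drift, pulse,
                                       atol=1e-9)

    def test_per_beat_amplitude_follows_respiratory_modulation(self):
        cfg = ps.default_config("D", seed=5, noise_sd=0.0, drift_amp=0.0,
                                heart_rate_sd=0.0, resp_mod_depth=0.2)
        rec, comp = ps.generate_recording(cfg, return_components=True)
        pulse = comp["z_100k"][1]
        beats = rec.beat_indices
        edges = np.concatenate(([0], (beats[:-1] + beats[1:]) // 2,
                                [len(pulse)]))
        omega = 2 * np.pi * cfg.resp_rate / 60.0
        for pk, lo, hi in list(zip(beats, edges[:-1], edges[1:]))[1:-1]:
            expected = cfg.delta_z_amp * (
                1 + cfg.resp_mod_depth * np.sin(omega * pk / cfg.fs))
            got = pulse[lo:hi].max() - pulse[lo:hi].min()
            assert got == pytest.approx(expected, rel=1e-6)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            ps.default_config("A", duration=0.3).validate()

    def test_seed_determines_output_bit_exactly(self):
        cfg = ps.default_config("B", seed=42, duration=5.0)
        r1, r2 = ps.generate_recording(cfg), ps.generate_recording(cfg)
        for ch in r1.channels:
            np.testing.assert_array_equal(r1.channels[ch], r2.channels[ch])
        np.testing.assert_array_equal(r1.beat_indices, r2.beat_indices)


class TestMakeDataset:
    def test_five_classes_times_three_measurements(self):
        recs = ps.make_dataset(None, 3, seed=1, duration=3.0)
        assert len(recs) == 15
        labels = [r.label for r in recs]
        assert all(labels.count(c) == 3 for c in ARTERY_CLASSES)

    def test_zero_recordings_gives_empty_dataset(self):
        assert ps.make_dataset(None, 0, seed=1, duration=3.0) == []

    def test_master_seed_reproduces_dataset(self):
        a = ps.make_dataset(None, 2, seed=9, duration=3.0)
        b = ps.make_dataset(None, 2, seed=9, duration=3.0)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.channels["rppg"],
                                          rb.channels["rppg"])

    def test_missing_class_rejected(self):
        cfgs = {c: ps.default_config(c, duration=3.0) for c in "ABCD"}
        with pytest.raises(ValueError, match="missing"):
            ps.make_dataset(cfgs, 1)


class TestClassSeparation:
    @staticmethod
    def _norm_template(cfg):
        t = ps.pulse_template(cfg.morphology, 1000, 1.0)
        return (t - t.mean()) / t.std()

    def test_default_morphologies_are_pairwise_distinct(self):
        temps = {c: self._norm_template(ps.default_config(c))
                 for c in ARTERY_CLASSES}
        for a in ARTERY_CLASSES:
            for b in ARTERY_CLASSES:
                if a < b:
                    mse = np.mean((temps[a] - temps[b]) ** 2)
                    assert mse > 1e-4, (a, b)

    def test_null_mode_morphologies_are_identical(self):
        temps = [self._norm_template(ps.default_config(c, null_mode=True))
                 for c in ARTERY_CLASSES]
        for t in temps[1:]:
            assert np.mean((temps[0] - t) ** 2) == 0.0


def test_recording_roundtrips_through_csv(tmp_path, clean_config):
    rec = ps.generate_recording(ps.default_config("E", seed=3, duration=3.0))
    ps.synthdata.save_recording(rec, tmp_path / "rec.csv")
    back = ps.synthdata.load_recording(tmp_path / "rec.csv")
    assert back.label == rec.label and back.fs == rec.fs
    np.testing.assert_array_equal(back.beat_indices, rec.beat_indices)
    np.testing.assert_allclose(back.channels["z_50k"], rec.channels["z_50k"],
                               rtol=1e-8)
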