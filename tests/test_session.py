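"""Session I/O and the notch / artifact-mask / RMS preprocessing chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from gammashift import session as sess
from gammashift.session import (
    LFPSession,
    TrialEvents,
    mask_artifacts,
    notch_60,
    preprocess,
    read_session,
    rms_normalize,
    write_session,
)

FS = 2000.0


def _tone(freq, seconds=10.0, fs=FS, amp=1.0):
    t = np.arange(0, seconds, 1 / fs)
    return amp * np.sin(2 * np.pi * freq * t)


def _rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestTrialEvents:
    def test_two_trial_toy_parse(self, tmp_path):
        lfp = pd.DataFrame({"time_s": np.arange(0, 40, 1 / FS)})
        lfp["voltage_uV"] = 0.1
        lfp.to_csv(tmp_path / "lfp.csv", index=False)
        pd.DataFrame(
            {
                "trial_id": [1, 2],
                "phase": ["ED", "ED"],
                "t_start_s": [0.0, 20.0],
                "t_dig_s": [9.0, 27.0],
                "outcome": ["correct", "incorrect"],
            }
        ).to_csv(tmp_path / "ev.csv", index=False)
        session, events = read_session(tmp_path / "lfp.csv", tmp_path / "ev.csv")
        assert len(events) == 2
        assert events.durations == pytest.approx([9.0, 7.0])
        assert session.sampling_rate == pytest.approx(FS)

    def test_dig_before_start_rejected(self):
        df = pd.DataFrame(
            {
                "trial_id": [1],
                "phase": ["ED"],
                "t_start": [5.0],
                "t_dig": [4.0],
                "outcome": ["correct"],
            }
        )
        with pytest.raises(ValueError, match="t_dig"):
            TrialEvents(df)

    def test_overlapping_trials_rejected(self):
        df = pd.DataFrame(
            {
                "trial_id": [1, 2],
                "phase": ["ED", "ED"],
                "t_start": [0.0, 5.0],
                "t_dig": [8.0, 12.0],
                "outcome": ["correct", "correct"],
            }
        )
        with pytest.raises(ValueError, match="overlap"):
            TrialEvents(df)

    def test_round_trip(self, tmp_path, small_session):
        session, events = small_session
        write_session(session, events, tmp_path / "l.csv", tmp_path / "e.csv")
        session2, events2 = read_session(tmp_path / "l.csv", tmp_path / "e.csv")
        assert session2.sampling_rate == pytest.approx(session.sampling_rate, rel=1e-6)
        np.testing.assert_allclose(session2.samples, session.samples, atol=1e-8)
        np.testing.assert_allclose(
            events2.table["t_dig"], events.table["t_dig"], atol=1e-9
        )


class TestNotch:
    def test_60hz_tone_removed(self):
        x = _tone(60)
        y = notch_60(x, FS)
        assert _rms(y[4000:-4000]) < 0.1 * _rms(x[4000:-4000])

    def test_65hz_tone_spared(self):
        x = _tone(65)
        y = notch_60(x, FS)
        assert _rms(y[4000:-4000]) == pytest.approx(_rms(x[4000:-4000]), rel=0.05)

    @pytest.mark.parametrize("freq", [50.0, 70.0])
    def test_neighbours_attenuated_below_1db(self, freq):
        x = _tone(freq)
        y = notch_60(x, FS)
        db = 20 * np.log10(_rms(y[4000:-4000]) / _rms(x[4000:-4000]))
        assert db > -1.0

    def test_zero_in_zero_out(self):
        y = notch_60(np.zeros(5000), FS)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_zero_phase(self):
        """Cross-correlation of a band-limited input with its filtered copy
        peaks at lag zero: forward-backward filtering adds no delay."""
        rng = np.random.default_rng(0)
        white = rng.standard_normal(20000)
        b, a = signal.butter(4, [10, 30], btype="band", fs=FS)
        x = signal.filtfilt(b, a, white)
        y = notch_60(x, FS)
        lags = np.arange(-50, 51)
        xc = [np.dot(x[200:-200], np.roll(y, L)[200:-200]) for L in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_bad_bandwidth(self):
        with pytest.raises(ValueError):
            notch_60(np.zeros(100), FS, bandwidth=0.0)


class TestMaskArtifacts:
    def test_constant_signal_unmasked(self):
        assert not mask_artifacts(np.full(100, 3.3)).any()

    def test_gaussian_tail_fraction(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(1_000_000)
        frac = mask_artifacts(x, k=3.0).mean()
        assert frac == pytest.approx(0.0027, abs=5e-4)

    def test_huge_spike_masked(self, rng):
        x = rng.standard_normal(10_000)
        x[1234] = 100.0
        assert mask_artifacts(x)[1234]

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_brute_force(self, values):
        x = np.array(values)
        mask = mask_artifacts(x, k=3.0)
        mu, sd = x.mean(), x.std()
        brute = (
            np.zeros(x.size, bool)
            if sd == 0
            else np.array([abs(v - mu) > 3.0 * sd for v in x])
        )
        np.testing.assert_array_equal(mask, brute)


class TestRmsNormalize:
    def test_alternating_threes(self):
        out = rms_normalize(np.array([3.0, -3.0, 3.0, -3.0]))
        np.testing.assert_allclose(out, [1.0, -1.0, 1.0, -1.0])

    def test_unmasked_rms_is_one(self, rng):
        x = rng.standard_normal(5000) * 17.0
        mask = rng.random(5000) < 0.1
        out = rms_normalize(x, mask)
        assert _rms(out[~mask]) == pytest.approx(1.0)

    @given(st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(512)
        np.testing.assert_allclose(rms_normalize(c * x), rms_normalize(x), rtol=1e-10)

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError, match="masked"):
            rms_normalize(np.ones(10), np.ones(10, bool))


class TestPreprocess:
    def test_output_rms_one(self, preprocessed):
        clean, _ = preprocessed
        assert clean.normalized
        assert _rms(clean.samples[~clean.artifact_mask]) == pytest.approx(1.0)

    def test_matches_manual_two_pass(self, small_session):
        raw, _ = small_session
        clean = preprocess(raw)
        notched = notch_60(raw.samples, raw.sampling_rate)
        mask = mask_artifacts(notched)
        manual = notched / _rms(notched[~mask])
        np.testing.assert_array_equal(clean.artifact_mask, mask)
        np.testing.assert_allclose(clean.samples, manual, rtol=1e-10)

    def test_artifact_samples_masked(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(60_000)
        x[30_000:30_010] += 400.0
        raw = LFPSession(x, sampling_rate=FS)
        clean = preprocess(raw)
        assert clean.artifact_mask[30_000:30_010].all()

    def test_near_idempotent(self, preprocessed):
        clean, _ = preprocessed
        again = preprocess(clean)
        rms = _rms(again.samples[~again.artifact_mask])
        assert abs(rms - 1.0) < 0.01

    def test_preserves_timing(self, small_session):
        raw, _ = small_session
        clean = preprocess(raw)
        assert clean.n_samples == raw.n_samples
        assert clean.sampling_rate == raw.sampling_rate
        assert clean.t0 == raw.t0


def test_nan_in_unmasked_samples_rejected():
    x = np.zeros(100)
    x[3] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        LFPSession(x)
    mask = np.zeros(100, bool)
    mask[3] = True
    sess.LFPSession(x, artifact_mask=mask)  # masked NaN is fine
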