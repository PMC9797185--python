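"""Wavelet power, normalization, task windows, and the trial-power table."""

import numpy as np
import pandas as pd
import pytest

from gammashift import spectral
from gammashift.session import LFPSession, TrialEvents
from gammashift.spectral import (
    BandSpec,
    Spectrogram,
    build_trial_table,
    normalize_power,
    pre_post_choice_difference,
    trial_window_spectra,
    wavelet_power,
    window_band_power,
)

FS = 2000.0


def _tone(freq, seconds=6.0, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(0, seconds, 1 / FS))


class TestWaveletPower:
    def test_tone_peak_at_its_frequency(self):
        spec = wavelet_power(_tone(65.0), FS, np.arange(30.0, 121.0))
        avg = spec.power[:, 2000:-2000].mean(axis=1)
        peak = spec.freqs[np.argmax(avg)]
        assert 62 <= peak <= 68

    def test_tone_power_amplitude_calibrated(self):
        """L1 normalization: a unit sinusoid has peak power 1 at its own
        frequency."""
        spec = wavelet_power(_tone(65.0), FS, np.array([65.0]))
        assert spec.power[0, 2000:-2000].mean() == pytest.approx(1.0, rel=0.01)

    def test_white_noise_is_spectrally_flat_enough(self, rng):
        x = rng.standard_normal(int(10 * FS))
        spec = wavelet_power(x, FS, np.arange(10.0, 201.0, 5.0))
        avg = spec.power[:, 2000:-2000].mean(axis=1)
        assert avg.max() < 3 * np.median(avg)

    def test_zero_signal_zero_power(self):
        spec = wavelet_power(np.zeros(4000), FS, np.arange(10.0, 100.0, 10.0))
        np.testing.assert_allclose(spec.power, 0.0, atol=1e-20)

    def test_power_monotone_in_amplitude(self):
        totals = [
            wavelet_power(_tone(40.0, amp=a), FS, np.arange(20.0, 61.0, 5.0)).power.sum()
            for a in (0.5, 1.0, 2.0)
        ]
        assert totals[0] < totals[1] < totals[2]

    def test_grid_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            wavelet_power(np.zeros(1000), FS, np.array([999.0, 1001.0]))


class TestNormalizePower:
    def _spec(self, rng):
        p = rng.random((5, 100)) + 0.5
        return Spectrogram(np.arange(5.0) + 1, np.arange(100.0) / FS, p)

    def test_row_mean_reference_gives_unit_rows(self, rng):
        spec = self._spec(rng)
        out = normalize_power(spec, spec.power.mean(axis=1))
        np.testing.assert_allclose(out.power.mean(axis=1), 1.0)

    def test_identity_reference(self, rng):
        spec = self._spec(rng)
        out = normalize_power(spec, np.ones(5))
        np.testing.assert_array_equal(out.power, spec.power)

    def test_invariant_to_global_rescale(self, rng):
        spec = self._spec(rng)
        scaled = Spectrogram(spec.freqs, spec.times, 7.3 * spec.power)
        a = normalize_power(spec, spec.power.mean(axis=1))
        b = normalize_power(scaled, scaled.power.mean(axis=1))
        np.testing.assert_allclose(a.power, b.power, rtol=1e-12)

    def test_zero_reference_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            normalize_power(self._spec(rng), np.array([1.0, 1.0, 0.0, 1.0, 1.0]))


class TestWindowBandPower:
    def test_constant_matrix_returns_constant(self):
        spec = Spectrogram(
            np.arange(1.0, 11.0), np.arange(0, 2, 1 / FS), np.full((10, 4000), 2.5)
        )
        for band in (BandSpec(1, 4, "a"), BandSpec(5, 10, "b")):
            assert window_band_power(spec, (0.5, 1.5), band) == pytest.approx(2.5)

    def test_band_ranking_on_tone(self):
        spec = wavelet_power(_tone(65.0), FS, np.arange(30.0, 121.0))
        mid = (1.5, 4.5)
        assert window_band_power(spec, mid, BandSpec(62, 67, "65hz")) > window_band_power(
            spec, mid, BandSpec(90, 120, "hg")
        )

    def test_zero_length_window_rejected(self):
        spec = Spectrogram(np.arange(1.0, 5.0), np.arange(0, 1, 1 / FS), np.ones((4, 2000)))
        with pytest.raises(ValueError, match="length"):
            window_band_power(spec, (0.5, 0.5), BandSpec(1, 4, "a"))

    def test_fully_masked_window_is_nan(self):
        valid = np.ones(2000, bool)
        valid[1000:1500] = False
        spec = Spectrogram(
            np.arange(1.0, 5.0), np.arange(0, 1, 1 / FS), np.ones((4, 2000)), valid
        )
        assert np.isnan(window_band_power(spec, (0.5, 0.75), BandSpec(1, 4, "a")))


def _toy_session_with_durations(durations, rng, gap=4.0):
    """Noise session with handcrafted trial durations."""
    starts, digs, t = [], [], 5.0
    for d in durations:
        starts.append(t)
        digs.append(t + d)
        t = t + d + 3.0 + gap
    n = int((t + 5.0) * FS)
    session = LFPSession(rng.standard_normal(n), FS, normalized=True)
    n = len(durations)
    events = TrialEvents(
        pd.DataFrame(
            {
                "trial_id": np.arange(1, n + 1),
                "phase": "ED",
                "t_start": starts,
                "t_dig": digs,
                "outcome": (["correct", "incorrect"] * (n // 2 + 1))[:n],
            }
        )
    )
    return session, events


class TestTrialTable:
    def test_exclusion_boundary_is_strict(self, rng):
        session, events = _toy_session_with_durations([5.9, 6.0, 6.1], rng)
        table = build_trial_table(
            session, events, bands=[BandSpec(62, 67, "65hz")], freqs=np.arange(60.0, 70.0)
        )
        kept = ~table.groupby("trial_id")["excluded"].first()
        assert list(kept) == [False, False, True]
        reasons = table[table["excluded"]]["reason"].unique()
        assert set(reasons) == {"duration<6s"}

    def test_record_cardinality(self, rng):
        session, events = _toy_session_with_durations([8.0, 9.0], rng)
        table = build_trial_table(
            session,
            events,
            bands=[BandSpec(62, 67, "65hz")],
            freqs=np.arange(60.0, 70.0),
            windows=("baseline", "choice"),
        )
        assert len(table) == 2 * 2 * 1

    def test_translation_invariance(self, small_cfg, preprocessed):
        """Shifting the session clock leaves every band power unchanged."""
        clean, events = preprocessed
        freqs = np.arange(60.0, 70.0)
        bands = [BandSpec(62, 67, "65hz")]
        t1 = build_trial_table(clean, events, bands=bands, freqs=freqs)
        shifted = LFPSession(
            clean.samples,
            clean.sampling_rate,
            t0=clean.t0 + 11.5,
            artifact_mask=clean.artifact_mask,
            normalized=True,
        )
        t2 = build_trial_table(shifted, events.shifted(11.5), bands=bands, freqs=freqs)
        np.testing.assert_allclose(
            t1["power"].to_numpy(), t2["power"].to_numpy(), rtol=1e-6
        )

    def test_matches_per_trial_oracle(self, preprocessed):
        """The batched window engine equals a brute-force route through the
        full-session spectrogram (computed trial by trial)."""
        clean, events = preprocessed
        freqs = np.array([40.0, 64.5, 100.0])
        grid, spectra = trial_window_spectra(
            clean, events, freqs, windows=("choice",), normalize=False
        )
        spec = wavelet_power(
            clean.samples, clean.sampling_rate, freqs, mask=clean.artifact_mask
        )
        for i in range(4):
            td = events.table["t_dig"].iloc[i]
            brute = [
                window_band_power(spec, (td - 3, td), BandSpec(f - 0.4, f + 0.4, "x"))
                for f in freqs
            ]
            np.testing.assert_allclose(brute, spectra["choice"][i], rtol=2e-2)

    def test_baseline_normalization_makes_baseline_unity(self, trial_table):
        base = trial_table[
            (trial_table["window"] == "baseline") & (trial_table["band"] == "65hz")
        ]
        assert base["power"].mean() == pytest.approx(1.0, rel=0.05)


class TestPrePostChoice:
    def _table(self, n, diffs, outcomes, excluded=None):
        rows = []
        excluded = excluded or [False] * n
        for i in range(n):
            for window, p in (("choice", 1.0 + diffs[i]), ("post_choice", 1.0)):
                rows.append(
                    {
                        "animal_id": "A1",
                        "trial_id": i + 1,
                        "phase": "ED",
                        "outcome": outcomes[i],
                        "window": window,
                        "band": "65hz",
                        "power": p,
                        "duration_s": 10.0,
                        "excluded": excluded[i],
                        "reason": "",
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_pre_post_gives_zero(self):
        table = self._table(4, [0.0] * 4, ["correct"] * 4)
        out = pre_post_choice_difference(table)
        np.testing.assert_allclose(out["difference"], 0.0)

    def test_first_n_selection_in_trial_order(self):
        table = self._table(8, list(range(8)), ["correct"] * 8)
        out = pre_post_choice_difference(table, first_n=5)
        assert list(out["trial_id"]) == [1, 2, 3, 4, 5]

    def test_excluded_trials_skipped_before_selection(self):
        table = self._table(
            7, list(range(7)), ["correct"] * 7, excluded=[True] + [False] * 6
        )
        out = pre_post_choice_difference(table, first_n=5)
        assert list(out["trial_id"]) == [2, 3, 4, 5, 6]

    def test_pre_dig_bursts_give_positive_differences(self, trial_table, preprocessed):
        _, events = preprocessed
        out = pre_post_choice_difference(trial_table)
        correct = out[out["outcome"] == "correct"]
        assert (correct["difference"] > 0).all()
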