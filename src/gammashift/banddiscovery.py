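"""Identify the outcome-discriminative frequency band within the gamma span.

The procedure that singled out 62–67 Hz: for every correct trial, find the
frequency in the 30–120 Hz gamma span (avoiding the 58–62 Hz line-noise
neighbourhood) where that trial's choice-window power most exceeds the mean
incorrect-trial spectrum; then select the fixed-width window that captures
the most per-trial peaks, breaking ties by the integrated mean
correct−incorrect difference, then toward the lower band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .spectral import BandSpec


@dataclass(frozen=True)
class BandSearchConfig:
    """Search space for the discriminative band.

    ``span`` is the closed gamma range searched; ``excluded_zone`` is an
    open interval around the power-line frequency that neither per-trial
    peaks nor candidate bands may enter (its endpoints remain eligible:
    trials peaking exactly at 58 Hz are informative); ``band_width`` is the
    number of integer-Hz frequencies in a candidate band, so width 6 gives
    bands like [62, 67].
    """

    span: tuple[float, float] = (30.0, 120.0)
    excluded_zone: tuple[float, float] = (58.0, 62.0)
    band_width: int = 6
    min_trials: int = 5

    def __post_init__(self) -> None:
        if not (self.span[0] < self.excluded_zone[0] < self.excluded_zone[1] < self.span[1]):
            raise ValueError("excluded_zone must lie strictly inside span")
        if self.band_width <= 0:
            raise ValueError("band_width must be positive")

    def eligible(self, freqs: np.ndarray) -> np.ndarray:
        """Frequencies admissible for per-trial peaks."""
        f = np.asarray(freqs, dtype=float)
        in_span = (f >= self.span[0]) & (f <= self.span[1])
        in_zone = (f > self.excluded_zone[0]) & (f < self.excluded_zone[1])
        return in_span & ~in_zone

    def candidate_bands(self) -> list[BandSpec]:
        """Integer-Hz candidate windows disjoint from the excluded zone."""
        out = []
        lo0 = int(np.ceil(self.span[0]))
        hi_max = int(np.floor(self.span[1]))
        for lo in range(lo0, hi_max - self.band_width + 2):
            hi = lo + self.band_width - 1
            if hi > hi_max:
                break
            if hi <= self.excluded_zone[0] or lo >= self.excluded_zone[1]:
                out.append(BandSpec(float(lo), float(hi), f"{lo}-{hi}Hz"))
        if not out:
            raise ValueError("no admissible candidate band in span")
        return out


@dataclass
class BandReport:
    """Outcome of a band search, serializable to JSON."""

    band: BandSpec
    peak_freqs: np.ndarray = field(repr=False)
    diff_curve: np.ndarray = field(repr=False)
    freqs: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        hist_f, counts = np.unique(self.peak_freqs, return_counts=True)
        return {
            "selected_band": {"lo": self.band.lo, "hi": self.band.hi, "label": self.band.label},
            "peak_histogram": {float(f): int(c) for f, c in zip(hist_f, counts)},
            "difference_curve": {
                "freqs": self.freqs.tolist(),
                "mean_correct_minus_incorrect": self.diff_curve.tolist(),
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def per_trial_peak_freq(
    correct_spectra: np.ndarray,
    incorrect_mean: np.ndarray,
    freqs: np.ndarray,
    config: BandSearchConfig = BandSearchConfig(),
) -> np.ndarray:
    """Frequency of maximal correct-minus-incorrect power, per correct trial.

    ``correct_spectra`` is (n_correct_trials, n_freqs) choice-window power;
    ``incorrect_mean`` the mean incorrect-trial spectrum on the same grid.
    Ties break toward the lower frequency.
    """
    C = np.atleast_2d(np.asarray(correct_spectra, dtype=float))
    m = np.asarray(incorrect_mean, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if m.size == 0 or not np.all(np.isfinite(m)):
        raise ValueError("incorrect-trial mean spectrum is empty or non-finite")
    if C.shape[1] != freqs.size or m.size != freqs.size:
        raise ValueError("spectra and frequency grid sizes disagree")
    if C.shape[0] < config.min_trials:
        raise ValueError(
            f"need at least {config.min_trials} correct trials, got {C.shape[0]}"
        )
    ok = config.eligible(freqs)
    if not ok.any():
        raise ValueError("no eligible frequencies in span")
    diff = C - m[None, :]
    sub = diff[:, ok]
    # argmax returns the first (lowest-frequency) maximizer
    return freqs[ok][np.argmax(sub, axis=1)]


def select_band(
    peak_freqs: np.ndarray,
    diffs: np.ndarray,
    freqs: np.ndarray,
    config: BandSearchConfig = BandSearchConfig(),
) -> BandSpec:
    """Fixed-width band capturing the most per-trial peaks.

    Primary criterion: count of per-trial peak frequencies inside the
    candidate band (closed interval). Ties break by the integrated mean
    correct−incorrect difference over the band, then toward the lower band.
    """
    peaks = np.asarray(peak_freqs, dtype=float)
    diffs = np.asarray(diffs, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    best = None
    best_key = None
    for band in config.candidate_bands():
        count = int(np.sum((peaks >= band.lo) & (peaks <= band.hi)))
        sel = band.contains(freqs)
        integral = float(np.sum(diffs[sel])) if sel.any() else 0.0
        key = (count, integral, -band.lo)
        if best_key is None or key > best_key:
            best, best_key = band, key
    return best


def discover_band(
    correct_spectra: np.ndarray,
    incorrect_spectra: np.ndarray,
    freqs: np.ndarray,
    config: BandSearchConfig = BandSearchConfig(),
) -> BandReport:
    """Run the full search from per-trial choice-window spectra.

    ``incorrect_spectra`` is (n_incorrect_trials, n_freqs); its mean is the
    comparison spectrum (trial-paired comparison is not used).
    """
    I = np.atleast_2d(np.asarray(incorrect_spectra, dtype=float))
    if I.size == 0:
        raise ValueError("no incorrect trials")
    incorrect_mean = I.mean(axis=0)
    peaks = per_trial_peak_freq(correct_spectra, incorrect_mean, freqs, config)
    C = np.atleast_2d(np.asarray(correct_spectra, dtype=float))
    diff_curve = C.mean(axis=0) - incorrect_mean
    band = select_band(peaks, diff_curve, freqs, config)
    return BandReport(band, peaks, diff_curve, np.asarray(freqs, dtype=float))
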