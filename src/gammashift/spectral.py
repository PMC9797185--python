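"""Morlet wavelet time-frequency analysis and task-window band power.

The continuous wavelet transform uses an analytic Morlet wavelet applied in
the frequency domain with L1 (amplitude) normalization, so the power of a
unit-amplitude sinusoid at frequency f0 peaks exactly at f0 with value 1.
L2-normalized implementations tilt the constant-Q response toward lower
frequencies by ~1%, which matters when bands are resolved at 1 Hz.

Task windows are half-open intervals on the session clock:

* baseline     = [t_start, t_start + 3 s)
* choice       = [t_dig − 3 s, t_dig)
* post_choice  = [t_dig, t_dig + 3 s)

Trials whose start-to-dig latency does not exceed 6 s are flagged excluded
(their baseline and choice windows would overlap); they remain in the table
so that analyses which ignore the latency rule (the outcome decoder) can
still use them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from .session import LFPSession, TrialEvents

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 3.0  #: seconds, all three task windows
MIN_TRIAL_DURATION = 6.0  #: seconds; a kept trial must be strictly longer

WINDOW_KINDS = ("baseline", "choice", "post_choice")


@dataclass(frozen=True)
class BandSpec:
    """Closed frequency band [lo, hi] in Hz with a display label."""

    lo: float
    hi: float
    label: str

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("band lo must be < hi")

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs, dtype=float)
        return (f >= self.lo) & (f <= self.hi)


#: The discriminative 65-Hz range plus the standard comparison bands.
CANONICAL_BANDS = (
    BandSpec(62, 67, "65hz"),
    BandSpec(1, 4, "delta"),
    BandSpec(4, 12, "theta"),
    BandSpec(12, 40, "beta"),
    BandSpec(90, 120, "high_gamma"),
    BandSpec(120, 200, "very_high"),
)
#: The broad gamma span searched during band discovery.
GAMMA_SPAN = BandSpec(30, 120, "gamma_span")


@dataclass(frozen=True)
class WindowSpec:
    """Task window anchored to a trial event.

    ``kind`` names the window; ``anchor`` is the event it is measured from
    (``t_start`` or ``t_dig``); the window is [anchor+offset,
    anchor+offset+length).
    """

    kind: str
    anchor: str
    offset: float
    length: float = WINDOW_LENGTH


TASK_WINDOWS = {
    "baseline": WindowSpec("baseline", "t_start", 0.0),
    "choice": WindowSpec("choice", "t_dig", -WINDOW_LENGTH),
    "post_choice": WindowSpec("post_choice", "t_dig", 0.0),
}


def resolve_window(window: WindowSpec, t_start: float, t_dig: float) -> tuple[float, float]:
    """Return the (start, stop) session times of a window for one trial."""
    anchor = t_start if window.anchor == "t_start" else t_dig
    a = anchor + window.offset
    return a, a + window.length


@dataclass
class Spectrogram:
    """Frequency × time power matrix on the session clock.

    ``valid`` marks time columns free of masked samples; invalid columns are
    excluded from every window average.
    """

    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.power.shape != (self.freqs.size, self.times.size):
            raise ValueError("power must be (n_freqs, n_times)")
        if self.valid is None:
            self.valid = np.ones(self.times.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)


# ---------------------------------------------------------------------------
# Frequency grids and wavelet parameters
# ---------------------------------------------------------------------------

def linear_grid(lo: float = 1.0, hi: float = 200.0, step: float = 1.0) -> np.ndarray:
    """Linear frequency grid in Hz, the default for band analyses."""
    return np.arange(lo, hi + step / 2, step)


def log_grid(lo: float = 1.0, hi: float = 200.0, voices: int = 12) -> np.ndarray:
    """Logarithmic grid with ``voices`` frequencies per octave (heat maps)."""
    n = int(np.ceil(voices * np.log2(hi / lo)))
    f = lo * 2 ** (np.arange(n + 1) / voices)
    return f[f <= hi * (1 + 1e-12)]


def n_cycles_for(freqs: np.ndarray, n_cycles="auto") -> np.ndarray:
    """Cycles per wavelet at each frequency.

    ``"auto"`` uses clip(f/2, 3, 7): short wavelets at low frequencies keep
    the support inside the analysis padding; seven cycles above 14 Hz give
    ~9 Hz spectral resolution at 65 Hz, enough to separate the 62–67 Hz
    range from its neighbours.
    """
    f = np.asarray(freqs, dtype=float)
    if isinstance(n_cycles, str):
        if n_cycles != "auto":
            raise ValueError("n_cycles must be a number or 'auto'")
        return np.clip(f / 2.0, 3.0, 7.0)
    return np.broadcast_to(np.asarray(n_cycles, dtype=float), f.shape).copy()


def _morlet_kernels(freqs, n_cyc, fgrid):
    """Frequency-domain analytic Morlet filters, L1-normalized.

    Each row is H(f) = 2·exp(−(f−fc)²/(2σ_f²)) on the positive frequencies
    (zero elsewhere), with σ_f = fc / n_cycles. The factor 2 makes the
    complex response to cos(2π fc t) have unit magnitude at fc.
    """
    sigma_f = freqs / n_cyc
    H = 2.0 * np.exp(-((fgrid[None, :] - freqs[:, None]) ** 2) / (2.0 * sigma_f[:, None] ** 2))
    H[:, fgrid <= 0] = 0.0
    return H


def wavelet_power(
    samples: np.ndarray,
    sampling_rate: float,
    freqs: np.ndarray,
    n_cycles="auto",
    mask: np.ndarray | None = None,
    t0: float = 0.0,
) -> Spectrogram:
    """Continuous Morlet wavelet power of a signal.

    Returns squared magnitude of the analytic wavelet coefficient per
    frequency and sample. Masked samples are zero-filled before the
    transform and their time columns marked invalid, so they are excluded
    from every window mean downstream.
    """
    x = np.asarray(samples, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    if np.any(freqs <= 0) or np.any(freqs >= sampling_rate / 2):
        raise ValueError("frequency grid must lie in (0, Nyquist)")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        x = np.where(mask, 0.0, x)
    n_cyc = n_cycles_for(freqs, n_cycles)
    n = x.size
    # Pad so the longest wavelet does not wrap around circularly.
    halfwidth = int(np.ceil(3 * n_cyc.max() / (2 * np.pi * freqs.min()) * sampling_rate))
    nfft = sp_fft.next_fast_len(n + 2 * halfwidth)
    X = sp_fft.fft(x, nfft)
    fgrid = sp_fft.fftfreq(nfft, d=1.0 / sampling_rate)
    H = _morlet_kernels(freqs, n_cyc, fgrid)
    power = np.empty((freqs.size, n))
    for i in range(freqs.size):
        w = sp_fft.ifft(X * H[i])[:n]
        power[i] = np.abs(w) ** 2
    valid = None if mask is None else ~mask
    times = t0 + np.arange(n) / sampling_rate
    return Spectrogram(freqs, times, power, valid)


def normalize_power(spec: Spectrogram, reference: np.ndarray) -> Spectrogram:
    """Divide each frequency row by a per-frequency reference (A.U. scale)."""
    ref = np.asarray(reference, dtype=float)
    if ref.shape != spec.freqs.shape:
        raise ValueError("reference must have one value per frequency")
    if np.any(ref <= 0):
        raise ValueError("reference must be strictly positive at every frequency")
    return Spectrogram(spec.freqs, spec.times, spec.power / ref[:, None], spec.valid)


def window_band_power(spec: Spectrogram, interval: tuple[float, float], band: BandSpec) -> float:
    """Mean power over a band and a half-open time window [a, b).

    Returns NaN (with a logged reason) when every time column in the window
    is masked. Raises for an empty window or one outside the recording.
    """
    a, b = interval
    if not b > a:
        raise ValueError("window must have positive length")
    if a < spec.times[0] - 1e-9 or b > spec.times[-1] + 1.0 / max(len(spec.times), 1) + 1e-9:
        raise ValueError("window outside recorded time span")
    cols = (spec.times >= a) & (spec.times < b)
    fsel = band.contains(spec.freqs)
    if not fsel.any():
        raise ValueError(f"no frequency bins inside band {band.label}")
    use = cols & spec.valid
    if not use.any():
        logger.warning("window [%g, %g) fully masked", a, b)
        return float("nan")
    return float(spec.power[np.ix_(fsel, use)].mean())


# ---------------------------------------------------------------------------
# Batched per-trial window engine
# ---------------------------------------------------------------------------

def _extract_segments(session: LFPSession, starts: np.ndarray, length_s: float, pad_s: float):
    """Stack equal-length padded windows; reflect at recording edges.

    Returns (segments, keep) where segments is (n_windows, n_samples) of the
    padded signal and keep the matching unmasked-sample indicator.
    """
    fs = session.sampling_rate
    n_win = int(round(length_s * fs))
    n_pad = int(round(pad_s * fs))
    total = n_win + 2 * n_pad
    x = session.samples
    m = session.artifact_mask
    n = x.size
    segs = np.empty((starts.size, total))
    keep = np.empty((starts.size, total), dtype=bool)
    idx0 = np.round((starts - session.t0) * fs).astype(int) - n_pad
    for j, i0 in enumerate(idx0):
        idx = np.arange(i0, i0 + total)
        # reflect indices that fall outside the recording
        idx = np.abs(idx)
        idx = np.where(idx >= n, 2 * (n - 1) - idx, idx)
        if np.any(idx < 0) or np.any(idx >= n):
            raise ValueError("window (with padding) cannot be placed inside the recording")
        segs[j] = x[idx]
        keep[j] = ~m[idx]
    return segs, keep, n_pad, n_win


def auto_pad(freqs, n_cycles="auto") -> float:
    """Segment padding (s) covering the wavelet support at the lowest frequency."""
    f = np.asarray(freqs, dtype=float)
    n_cyc = n_cycles_for(f, n_cycles)
    i = int(np.argmin(f))
    return float(max(0.25, 3 * n_cyc[i] / (2 * np.pi * f[i])))


def _window_mean_power(segs, keep, n_pad, n_win, fs, freqs, n_cycles="auto", chunk=4):
    """Per-window, per-frequency mean Morlet power over unmasked columns.

    Processes frequencies in chunks to bound memory and works in single
    precision internally (power is averaged over thousands of samples, so
    float32 round-off is negligible against the float64 reference path).
    Masked samples are zero-filled before the transform and excluded from
    the mean.
    """
    freqs = np.asarray(freqs, dtype=float)
    n_cyc = n_cycles_for(freqs, n_cycles)
    nseg, total = segs.shape
    halfwidth = int(np.ceil(3 * np.max(n_cyc / freqs) / (2 * np.pi) * fs)) + 1
    nfft = sp_fft.next_fast_len(total + 2 * halfwidth)
    X = sp_fft.fft(np.where(keep, segs, 0.0).astype(np.float32), nfft, axis=1)
    fgrid = sp_fft.fftfreq(nfft, d=1.0 / fs)
    sl = slice(n_pad, n_pad + n_win)
    kw = keep[:, sl]
    denom = kw.sum(axis=1).astype(float)
    if np.any(denom == 0):
        logger.warning("%d window(s) fully masked", int((denom == 0).sum()))
    out = np.empty((nseg, freqs.size))
    for lo in range(0, freqs.size, chunk):
        hi = min(lo + chunk, freqs.size)
        H = _morlet_kernels(freqs[lo:hi], n_cyc[lo:hi], fgrid).astype(np.float32)
        W = sp_fft.ifft(X[:, None, :] * H[None, :, :], axis=2)[:, :, :total]
        P = np.abs(W[:, :, sl]).astype(np.float64) ** 2
        with np.errstate(invalid="ignore"):
            out[:, lo:hi] = np.where(kw[:, None, :], P, 0.0).sum(axis=2) / denom[:, None]
    return out


def trial_window_spectra(
    session: LFPSession,
    events: TrialEvents,
    freqs: np.ndarray | None = None,
    windows=WINDOW_KINDS,
    pad="auto",
    n_cycles="auto",
    normalize: bool = True,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-trial, per-window power spectra, baseline-normalized.

    Returns ``(freqs, spectra)`` where ``spectra[kind]`` is an
    (n_trials, n_freqs) matrix of mean power in that window. Trials without
    a dig event get NaN rows for dig-anchored windows. When ``normalize``
    is true, every spectrum is divided per frequency by the session-wide
    mean baseline power (the arbitrary-units convention), so baseline rows
    average 1 at every frequency by construction.
    """
    if freqs is None:
        freqs = linear_grid()
    freqs = np.asarray(freqs, dtype=float)
    if pad == "auto":
        pad = auto_pad(freqs, n_cycles)
    df = events.table
    t_start = df["t_start"].to_numpy(float)
    t_dig = df["t_dig"].to_numpy(float)
    has_dig = ~np.isnan(t_dig)
    fs = session.sampling_rate

    spectra: dict[str, np.ndarray] = {}
    kinds = list(windows)
    if normalize and "baseline" not in kinds:
        kinds = ["baseline"] + kinds
    for kind in kinds:
        w = TASK_WINDOWS[kind]
        anchor = t_start if w.anchor == "t_start" else t_dig
        ok = ~np.isnan(anchor)
        starts = anchor[ok] + w.offset
        segs, keep, n_pad, n_win = _extract_segments(session, starts, w.length, pad)
        vals = np.full((len(df), freqs.size), np.nan)
        vals[ok] = _window_mean_power(segs, keep, n_pad, n_win, fs, freqs, n_cycles)
        spectra[kind] = vals

    if normalize:
        ref = np.nanmean(spectra["baseline"], axis=0)
        if np.any(~np.isfinite(ref)) or np.any(ref <= 0):
            raise ValueError("baseline reference power must be finite and positive")
        for kind in spectra:
            spectra[kind] = spectra[kind] / ref[None, :]
    spectra = {k: spectra[k] for k in windows}
    _ = has_dig
    return freqs, spectra


def build_trial_table(
    session: LFPSession,
    events: TrialEvents,
    bands=CANONICAL_BANDS,
    freqs: np.ndarray | None = None,
    windows=WINDOW_KINDS,
    animal_id: str = "A1",
    pad="auto",
    n_cycles="auto",
) -> pd.DataFrame:
    """One band-power record per trial × window × band.

    Columns: ``animal_id, trial_id, phase, outcome, window, band, power,
    duration_s, excluded, reason``. Power is in arbitrary units (A.U.) —
    per-frequency baseline-normalized. Trials whose dig latency does not
    exceed 6 s are flagged ``excluded`` with reason ``duration<6s``; trials
    without a dig event are flagged ``no_dig`` and carry NaN power in
    dig-anchored windows. Excluded records stay in the table because the
    outcome decoder uses all trials regardless of latency.
    """
    if freqs is None:
        freqs = linear_grid()
    grid, spectra = trial_window_spectra(
        session, events, freqs, windows=windows, pad=pad, n_cycles=n_cycles
    )
    df = events.table
    durations = events.durations
    rows = []
    for i in range(len(df)):
        no_dig = np.isnan(df["t_dig"].iloc[i])
        if no_dig:
            excluded, reason = True, "no_dig"
        elif not durations[i] > MIN_TRIAL_DURATION:
            excluded, reason = True, "duration<6s"
        else:
            excluded, reason = False, ""
        for kind in windows:
            for band in bands:
                sel = band.contains(grid)
                if not sel.any():
                    raise ValueError(f"no frequency bins inside band {band.label}")
                power = float(np.mean(spectra[kind][i, sel]))
                rows.append(
                    {
                        "animal_id": animal_id,
                        "trial_id": df["trial_id"].iloc[i],
                        "phase": df["phase"].iloc[i],
                        "outcome": df["outcome"].iloc[i],
                        "window": kind,
                        "band": band.label,
                        "power": power,
                        "duration_s": durations[i],
                        "excluded": excluded,
                        "reason": reason,
                    }
                )
    return pd.DataFrame(rows)


def pre_post_choice_difference(
    records: pd.DataFrame,
    band: str = "65hz",
    first_n: int = 5,
    phase: str = "ED",
) -> pd.DataFrame:
    """Pre-minus-post choice band power for the first eligible shift trials.

    For each of the first ``first_n`` non-excluded trials of ``phase`` (in
    trial order) returns ``choice − post_choice`` power in ``band``, with
    the trial outcome. Latency-excluded trials are dropped before the
    first-n selection. If fewer than ``first_n`` trials are eligible the
    difference is computed on those available.
    """
    sub = records[
        (records["band"] == band)
        & (records["phase"] == phase)
        & (~records["excluded"])
        & (records["window"].isin(["choice", "post_choice"]))
    ]
    wide = sub.pivot_table(
        index=["trial_id", "outcome"], columns="window", values="power"
    ).reset_index()
    if "choice" not in wide.columns or "post_choice" not in wide.columns:
        return pd.DataFrame(columns=["trial_id", "outcome", "difference"])
    wide = wide.sort_values("trial_id").head(first_n)
    out = pd.DataFrame(
        {
            "trial_id": wide["trial_id"].to_numpy(),
            "outcome": wide["outcome"].to_numpy(),
            "difference": (wide["choice"] - wide["post_choice"]).to_numpy(),
        }
    )
    if len(out) < first_n:
        logger.info("only %d of %d requested trials eligible", len(out), first_n)
    return out
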