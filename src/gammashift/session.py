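"""Session data model, CSV I/O, and the three-step LFP preprocessing chain.

A recording session couples a continuous local field potential (LFP) trace
with per-trial event timestamps (trial start, dig/choice, outcome).
Preprocessing follows a fixed order: zero-phase 60-Hz notch filtering,
3-SD artifact masking, and RMS normalization of the unmasked signal.

Artifact-contaminated samples are *masked*, never deleted, so that sample
indices stay aligned with event timestamps; masked samples are excluded
from the RMS denominator and from every downstream window average.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

DEFAULT_SAMPLING_RATE = 2000.0

PHASES = ("IA", "ED")
OUTCOMES = ("correct", "incorrect")

#: Required columns of the LFP CSV dialect.
LFP_COLUMNS = ["time_s", "voltage_uV"]
#: Required columns of the trial-events CSV dialect.
EVENT_COLUMNS = ["trial_id", "phase", "t_start_s", "t_dig_s", "outcome"]


@dataclass
class LFPSession:
    """Continuous LFP trace with sampling rate and artifact mask.

    Parameters
    ----------
    samples
        Voltage series in microvolts (unitless after RMS normalization).
    sampling_rate
        Samples per second; acquisition default is 2000 Hz.
    t0
        Session start time in seconds; sample ``i`` occurs at
        ``t0 + i / sampling_rate``.
    artifact_mask
        Boolean series, same length as ``samples``; ``True`` marks samples
        excluded from all analyses.
    normalized
        Whether the trace has been RMS-normalized (unitless).
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    t0: float = 0.0
    artifact_mask: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.samples.shape, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != self.samples.shape:
            raise ValueError("artifact_mask length must equal samples length")
        if np.isnan(self.samples[~self.artifact_mask]).any():
            raise ValueError("NaN among unmasked samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Sample index of session time ``t`` (rounded down)."""
        return int(np.floor((t - self.t0) * self.sampling_rate))


@dataclass
class TrialEvents:
    """Per-trial event table: start/dig timestamps, phase, and outcome.

    Backed by a :class:`pandas.DataFrame` with columns ``trial_id``,
    ``phase`` (IA or ED), ``t_start``, ``t_dig`` (seconds, session clock)
    and ``outcome`` (correct/incorrect); ``t_dig`` may be NaN for a trial
    in which no dig occurred.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table.reset_index(drop=True).copy()
        required = {"trial_id", "phase", "t_start", "t_dig", "outcome"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        bad_phase = ~df["phase"].isin(PHASES)
        if bad_phase.any():
            row = int(df.index[bad_phase][0])
            raise ValueError(f"row {row}: phase must be one of {PHASES}")
        has_dig = df["t_dig"].notna()
        bad_out = has_dig & ~df["outcome"].isin(OUTCOMES)
        if bad_out.any():
            row = int(df.index[bad_out][0])
            raise ValueError(f"row {row}: outcome must be one of {OUTCOMES}")
        bad_order = has_dig & (df["t_dig"] <= df["t_start"])
        if bad_order.any():
            row = int(df.index[bad_order][0])
            raise ValueError(f"row {row}: t_dig must exceed t_start")
        starts = df["t_start"].to_numpy(float)
        if np.any(np.diff(starts) <= 0):
            row = int(np.flatnonzero(np.diff(starts) <= 0)[0]) + 1
            raise ValueError(f"row {row}: trials must be ordered by t_start")
        ends = np.where(has_dig, df["t_dig"].to_numpy(float), starts)
        if np.any(starts[1:] < ends[:-1]):
            row = int(np.flatnonzero(starts[1:] < ends[:-1])[0]) + 1
            raise ValueError(f"row {row}: trials overlap")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def durations(self) -> np.ndarray:
        """Trial-start to dig latency in seconds (NaN when no dig)."""
        return (self.table["t_dig"] - self.table["t_start"]).to_numpy(float)

    def shifted(self, delta: float) -> "TrialEvents":
        """Return a copy with all timestamps shifted by ``delta`` seconds."""
        df = self.table.copy()
        df["t_start"] = df["t_start"] + delta
        df["t_dig"] = df["t_dig"] + delta
        return TrialEvents(df)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_session(lfp_path, events_path) -> tuple[LFPSession, TrialEvents]:
    """Read an LFP trace and trial events from their CSV files.

    Timestamps in both files are converted to seconds relative to the first
    LFP sample. The sampling rate is inferred from the time column and
    checked for uniformity.
    """
    lfp = pd.read_csv(lfp_path)
    missing = set(LFP_COLUMNS) - set(lfp.columns)
    if missing:
        raise ValueError(f"{lfp_path}: missing columns {sorted(missing)}")
    t = lfp["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"{lfp_path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{lfp_path}: time column must be uniformly increasing")
    fs = 1.0 / dt[0]
    t0 = t[0]
    session = LFPSession(lfp["voltage_uV"].to_numpy(float), sampling_rate=fs)

    ev = pd.read_csv(events_path)
    missing = set(EVENT_COLUMNS) - set(ev.columns)
    if missing:
        raise ValueError(f"{events_path}: missing columns {sorted(missing)}")
    events = TrialEvents(
        pd.DataFrame(
            {
                "trial_id": ev["trial_id"],
                "phase": ev["phase"],
                "t_start": ev["t_start_s"].astype(float) - t0,
                "t_dig": ev["t_dig_s"].astype(float) - t0,
                "outcome": ev["outcome"],
            }
        )
    )
    return session, events


def write_session(session: LFPSession, events: TrialEvents, lfp_path, events_path) -> None:
    """Write a session in the CSV dialect that :func:`read_session` accepts."""
    pd.DataFrame(
        {"time_s": session.times(), "voltage_uV": session.samples}
    ).to_csv(lfp_path, index=False)
    df = events.table
    pd.DataFrame(
        {
            "trial_id": df["trial_id"],
            "phase": df["phase"],
            "t_start_s": df["t_start"] + session.t0,
            "t_dig_s": df["t_dig"] + session.t0,
            "outcome": df["outcome"],
        }
    ).to_csv(events_path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing steps
# ---------------------------------------------------------------------------

def notch_60(
    samples: np.ndarray,
    sampling_rate: float,
    center: float = 60.0,
    bandwidth: float = 2.0,
) -> np.ndarray:
    """Zero-phase IIR band-stop filter removing line noise at ``center`` Hz.

    Forward-backward filtering (``filtfilt``) gives zero phase delay. The
    -3 dB bandwidth is ``bandwidth`` Hz per pass, narrow enough to leave
    50- and 70-Hz components attenuated by less than 1 dB.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if sampling_rate <= 2 * center:
        raise ValueError("sampling_rate must exceed twice the notch center")
    b, a = signal.iirnotch(center, center / bandwidth, fs=sampling_rate)
    return signal.filtfilt(b, a, np.asarray(samples, dtype=float))


def mask_artifacts(samples: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Flag samples deviating more than ``k`` SD from the whole-signal mean.

    The mean and standard deviation are computed once over the entire
    signal (not iteratively and not per trial). A constant signal yields
    an empty mask with a logged warning.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    sd = x.std()
    if sd == 0:
        logger.warning("constant signal: SD is zero, no samples masked")
        return np.zeros(x.shape, dtype=bool)
    return np.abs(x - x.mean()) > k * sd


def rms_normalize(samples: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Divide the signal by the RMS of its unmasked samples.

    After normalization the unmasked portion has RMS exactly 1; the output
    is invariant to rescaling of the input.
    """
    x = np.asarray(samples, dtype=float)
    if mask is None:
        mask = np.zeros(x.shape, dtype=bool)
    kept = x[~np.asarray(mask, dtype=bool)]
    if kept.size == 0:
        raise ValueError("all samples masked: cannot normalize")
    rms = np.sqrt(np.mean(kept**2))
    if rms == 0:
        raise ValueError("unmasked signal is identically zero")
    return x / rms


def preprocess(
    session: LFPSession,
    k: float = 3.0,
    notch_center: float = 60.0,
    notch_bandwidth: float = 2.0,
    rectify: bool = False,
) -> LFPSession:
    """Apply the fixed preprocessing chain: notch → artifact mask → RMS.

    Artifact detection runs on the notch-filtered trace; the resulting mask
    is OR-combined with any pre-existing mask, and masked samples are
    excluded from the RMS denominator. ``rectify=True`` additionally
    replaces the signal by its absolute value before normalization (an
    alternative reading of root-mean-square cleaning, off by default
    because rectification destroys the oscillatory sign structure the
    wavelet transform needs).

    Timestamps and trial structure are untouched: the output has the same
    length, sampling rate, and ``t0`` as the input.
    """
    notched = notch_60(session.samples, session.sampling_rate, notch_center, notch_bandwidth)
    mask = session.artifact_mask | mask_artifacts(notched, k=k)
    if rectify:
        notched = np.abs(notched)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normalized = rms_normalize(notched, mask)
    return LFPSession(
        normalized,
        sampling_rate=session.sampling_rate,
        t0=session.t0,
        artifact_mask=mask,
        normalized=True,
    )
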