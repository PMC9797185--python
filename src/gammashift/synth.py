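"""Synthetic LFP sessions and behavioral logs with known ground truth.

The LFP generator emulates the statistical structure the analysis assumes:
a 1/f^α pink-noise background, a 60-Hz line-noise sinusoid, sparse
high-amplitude biphasic artifacts, and an outcome-dependent gamma-band
(62–67 Hz by default) burst confined to the 3 s preceding the dig on each
trial. Every random draw flows from a single seeded generator per session,
so identical seed and configuration give bit-identical output.

The behavioral generator plays a parameterized agent through the
set-shifting task (initial acquisition, then an extradimensional shift)
until the 8-of-10 criterion or a trial cap.

Feature-level cohort generators (`generate_decoder_cohort`,
`generate_lmm_cohort`) produce trial-power tables directly, for decoder
calibration and mixed-model recovery studies where simulating voltage
traces adds nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal as sp_signal

from .behavior import (
    CRITERION_NEEDED,
    CRITERION_WINDOW,
    DIMENSIONS,
    BehaviorSession,
    RuleSpec,
    trials_to_criterion,
)
from .session import LFPSession, TrialEvents
from .spectral import WINDOW_LENGTH

MAX_ANALYSIS_FREQ = 200.0


@dataclass
class SynthConfig:
    """Parameters of a synthetic LFP session.

    Amplitudes are in µV. ``trial_duration`` is the (lo, hi) of a uniform
    start-to-dig latency distribution; the acquisition default of 8–60 s
    matches typical trial lengths in the task. ``noise_sd`` sets the pink
    background standard deviation; gamma burst amplitudes are the peak
    amplitude of an equivalent sinusoid (the band-limited burst is scaled
    to the matching RMS, amp/√2). ``gamma_mode`` is ``"noise"`` for
    amplitude-modulated band-limited noise or ``"tone"`` for a pure
    sinusoid at ``tone_freq`` (band center when None) used by oracle tests.
    """

    sampling_rate: float = 2000.0
    n_trials: int = 20
    trial_duration: tuple[float, float] = (8.0, 60.0)
    iti: float = 2.0
    lead_in: float = 5.0
    pink_exponent: float = 1.0
    noise_sd: float = 50.0
    line_amp: float = 20.0
    line_freq: float = 60.0
    artifact_rate: float = 2.0
    artifact_amp: float = 400.0
    gamma_band: tuple[float, float] = (62.0, 67.0)
    gamma_amp_correct: float = 30.0
    gamma_amp_incorrect: float = 0.0
    gamma_mode: str = "noise"
    tone_freq: float | None = None
    p_correct: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * MAX_ANALYSIS_FREQ:
            raise ValueError("sampling_rate must exceed twice the highest analysis frequency")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        lo, hi = self.trial_duration
        if lo <= 0 or hi < lo:
            raise ValueError("trial durations must be positive with lo <= hi")
        if self.artifact_rate < 0 or self.noise_sd < 0 or self.line_amp < 0:
            raise ValueError("rates and amplitudes must be nonnegative")
        if self.gamma_amp_correct < 0 or self.gamma_amp_incorrect < 0:
            raise ValueError("gamma amplitudes must be nonnegative")
        if not 0 <= self.p_correct <= 1:
            raise ValueError("p_correct must be in [0, 1]")
        if not 0 < self.gamma_band[0] < self.gamma_band[1]:
            raise ValueError("gamma_band must be an increasing positive interval")
        if self.gamma_mode not in ("noise", "tone"):
            raise ValueError("gamma_mode must be 'noise' or 'tone'")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SynthConfig":
        known = {k: v for k, v in mapping.items() if k in cls.__dataclass_fields__}
        unknown = set(mapping) - set(known)
        if unknown:
            raise ValueError(f"unknown SynthConfig fields: {sorted(unknown)}")
        for key in ("trial_duration", "gamma_band"):
            if key in known and isinstance(known[key], (list, tuple)):
                known[key] = tuple(known[key])
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^α noise by spectral shaping of white noise."""
    nfft = sp_fft.next_fast_len(n)
    white = rng.standard_normal(nfft)
    X = sp_fft.rfft(white)
    f = sp_fft.rfftfreq(nfft)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = sp_fft.irfft(X * scale, nfft)[:n]
    return x / x.std()


def _bandlimited_noise(n: int, fs: float, band: tuple[float, float], rng) -> np.ndarray:
    """Unit-RMS noise with support restricted to ``band`` Hz."""
    white = rng.standard_normal(n)
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    X[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(X, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _biphasic(width_samples: int) -> np.ndarray:
    """Unit-peak biphasic transient (derivative-of-Gaussian shape)."""
    t = np.linspace(-3, 3, width_samples)
    pulse = -t * np.exp(-(t**2) / 2)
    return pulse / np.abs(pulse).max()


def generate_lfp_session(config: SynthConfig) -> tuple[LFPSession, TrialEvents]:
    """Generate a continuous LFP trace plus ground-truth trial events.

    The trace is the sum of pink background, line-noise sinusoid,
    Poisson-timed biphasic artifacts, and per-trial gamma bursts confined
    to [t_dig − 3 s, t_dig) with amplitude set by the trial outcome.
    Trials are laid out sequentially with a 3-s post-dig allowance plus
    ``iti`` seconds between dig and the next start.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    lo, hi = config.trial_duration
    durations = rng.uniform(lo, hi, config.n_trials)
    outcomes = rng.random(config.n_trials) < config.p_correct

    t_start = np.empty(config.n_trials)
    t_dig = np.empty(config.n_trials)
    t = config.lead_in
    for i, d in enumerate(durations):
        t_start[i] = t
        t_dig[i] = t + d
        t = t_dig[i] + WINDOW_LENGTH + config.iti
    total_s = t + config.lead_in
    n = int(np.ceil(total_s * fs))

    x = config.noise_sd * pink_noise(n, config.pink_exponent, rng)
    if config.line_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += config.line_amp * np.sin(
            2 * np.pi * config.line_freq * np.arange(n) / fs + phase
        )

    if config.artifact_rate > 0:
        n_art = rng.poisson(config.artifact_rate * total_s / 60.0)
        for _ in range(n_art):
            width = int(rng.uniform(0.005, 0.020) * fs)
            i0 = rng.integers(0, n - width)
            x[i0 : i0 + width] += rng.choice([-1.0, 1.0]) * config.artifact_amp * _biphasic(width)

    win = int(round(WINDOW_LENGTH * fs))
    envelope = sp_signal.windows.tukey(win, alpha=0.25)
    for i in range(config.n_trials):
        amp = config.gamma_amp_correct if outcomes[i] else config.gamma_amp_incorrect
        if amp <= 0:
            continue
        i1 = int(round(t_dig[i] * fs))
        i0 = i1 - win
        if config.gamma_mode == "tone":
            f0 = config.tone_freq
            if f0 is None:
                f0 = 0.5 * (config.gamma_band[0] + config.gamma_band[1])
            burst = np.sin(2 * np.pi * f0 * np.arange(win) / fs)
        else:
            burst = _bandlimited_noise(win, fs, config.gamma_band, rng)
        burst = burst * envelope
        rms = np.sqrt(np.mean(burst**2))
        if rms > 0:
            burst *= (amp / np.sqrt(2.0)) / rms
        x[i0:i1] += burst

    events = TrialEvents(
        pd.DataFrame(
            {
                "trial_id": np.arange(1, config.n_trials + 1),
                "phase": "ED",
                "t_start": t_start,
                "t_dig": t_dig,
                "outcome": np.where(outcomes, "correct", "incorrect"),
            }
        )
    )
    return LFPSession(x, sampling_rate=fs), events


def band_snr(config: SynthConfig) -> float:
    """Burst-to-background RMS ratio inside the gamma band (analytic).

    Background band variance integrates the pink spectrum over the band as
    a fraction of its total over [1/60 Hz, Nyquist]; the line component is
    outside the band and ignored. The burst RMS is amp/√2.
    """
    lo, hi = config.gamma_band
    a = config.pink_exponent

    def integral(f1, f2):
        if a == 1.0:
            return np.log(f2 / f1)
        return (f2 ** (1 - a) - f1 ** (1 - a)) / (1 - a)

    fmin, fmax = 1.0 / 60.0, config.sampling_rate / 2.0
    frac = integral(lo, hi) / integral(fmin, fmax)
    band_sd = config.noise_sd * np.sqrt(frac)
    if band_sd == 0:
        return np.inf
    return float((config.gamma_amp_correct / np.sqrt(2.0)) / band_sd)


# ---------------------------------------------------------------------------
# Behavioral sessions
# ---------------------------------------------------------------------------

@dataclass
class ChoicePolicy:
    """Per-trial mixture over choice strategies.

    With probability ``p_perseverate`` the agent chooses by the previously
    rewarded rule, with ``p_rule`` by the currently active rule, otherwise
    it picks a pot at random. During IA there is no previous rule, so the
    perseveration mass folds into random choice.
    """

    p_perseverate: float = 0.3
    p_rule: float = 0.5
    p_random: float = 0.2

    def __post_init__(self) -> None:
        probs = (self.p_perseverate, self.p_rule, self.p_random)
        if any(p < 0 for p in probs) or not np.isclose(sum(probs), 1.0):
            raise ValueError("policy probabilities must be nonnegative and sum to 1")


@dataclass
class SynthBehaviorConfig:
    """Parameters of a synthetic set-shifting session."""

    ia_rule: RuleSpec = field(default_factory=lambda: RuleSpec("odor", "cinnamon"))
    ed_rule: RuleSpec = field(default_factory=lambda: RuleSpec("medium", "paper"))
    policy: ChoicePolicy = field(default_factory=ChoicePolicy)
    ia_p_rule: float = 0.85
    latency: tuple[float, float] = (8.0, 60.0)
    max_trials_per_phase: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ia_rule.dimension == self.ed_rule.dimension:
            raise ValueError("IA and ED rules must differ in dimension")
        if not 0 <= self.ia_p_rule <= 1:
            raise ValueError("ia_p_rule must be in [0, 1]")
        lo, hi = self.latency
        if lo <= 0 or hi < lo:
            raise ValueError("latencies must be positive with lo <= hi")


def _random_pots(rng) -> list[dict]:
    """Two pots pairing the stimuli; assignment randomized."""
    odors = list(DIMENSIONS["odor"])
    media = list(DIMENSIONS["medium"])
    rng.shuffle(odors)
    rng.shuffle(media)
    return [
        {"odor": odors[0], "medium": media[0]},
        {"odor": odors[1], "medium": media[1]},
    ]


def _choose(pots, rule: RuleSpec | None, rng) -> dict:
    if rule is None:
        return pots[rng.integers(2)]
    for pot in pots:
        if pot[rule.dimension] == rule.rewarded_stimulus:
            return pot
    raise RuntimeError("rule stimulus missing from pots")


def generate_behavior_session(config: SynthBehaviorConfig) -> BehaviorSession:
    """Simulate IA then ED phases until criterion or the trial cap.

    The ED phase continues until 8 of 10 consecutive trials are correct; a
    session hitting ``max_trials_per_phase`` first is flagged censored
    rather than raising.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    censored = False
    trial_id = 1
    for phase, rule, prev_rule in (
        ("IA", config.ia_rule, None),
        ("ED", config.ed_rule, config.ia_rule),
    ):
        outcomes: list[bool] = []
        while len(outcomes) < config.max_trials_per_phase:
            pots = _random_pots(rng)
            if phase == "IA":
                strategy = "rule" if rng.random() < config.ia_p_rule else "random"
            else:
                u = rng.random()
                if u < config.policy.p_perseverate:
                    strategy = "perseverate"
                elif u < config.policy.p_perseverate + config.policy.p_rule:
                    strategy = "rule"
                else:
                    strategy = "random"
            chosen = _choose(
                pots,
                {"rule": rule, "perseverate": prev_rule, "random": None}[strategy],
                rng,
            )
            correct = chosen[rule.dimension] == rule.rewarded_stimulus
            rows.append(
                {
                    "trial_id": trial_id,
                    "phase": phase,
                    "chosen_odor": chosen["odor"],
                    "chosen_medium": chosen["medium"],
                    "correct": correct,
                    "latency_s": rng.uniform(*config.latency),
                    "timeout": False,
                }
            )
            outcomes.append(correct)
            trial_id += 1
            if trials_to_criterion(outcomes, CRITERION_NEEDED, CRITERION_WINDOW) is not None:
                break
        else:
            censored = True
    return BehaviorSession(
        pd.DataFrame(rows), ia_rule=config.ia_rule, ed_rule=config.ed_rule, censored=censored
    )


# ---------------------------------------------------------------------------
# Feature-level cohorts
# ---------------------------------------------------------------------------

TRIAL_TYPES_CYCLE = ("baseline", "correct", "incorrect")


def generate_decoder_cohort(
    n_correct: int = 62,
    n_incorrect: int = 17,
    effect: float = 0.5,
    noise_sd: float = 0.5,
    baseline: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-trial 65-Hz choice-window power features with a known effect.

    Correct trials get ``baseline + effect`` mean power, incorrect trials
    ``baseline``, with Gaussian trial-to-trial noise. ``effect=0`` gives a
    null cohort. Default class sizes mirror a control cohort (62 correct,
    17 incorrect choice trials).
    """
    rng = np.random.default_rng(seed)
    n = n_correct + n_incorrect
    outcome = np.array(["correct"] * n_correct + ["incorrect"] * n_incorrect)
    rng.shuffle(outcome)
    power = baseline + effect * (outcome == "correct") + noise_sd * rng.standard_normal(n)
    return pd.DataFrame(
        {"trial_id": np.arange(1, n + 1), "outcome": outcome, "power": power}
    )


def generate_lmm_cohort(
    n_animals: int = 8,
    n_trials: int = 20,
    beta_correct: float = 0.5,
    beta_incorrect: float = 0.0,
    animal_sd: float = 0.3,
    noise_sd: float = 0.5,
    intercept: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Trial-level power rows from a known random-intercept model.

    Each animal contributes ``n_trials`` rows with trial types cycled
    through baseline / correct / incorrect; power = intercept + animal
    effect + type effect + noise.
    """
    rng = np.random.default_rng(seed)
    types = np.tile(np.array(TRIAL_TYPES_CYCLE), n_trials // 3 + 1)[:n_trials]
    rows = []
    for a in range(n_animals):
        u = animal_sd * rng.standard_normal()
        t = types.copy()
        rng.shuffle(t)
        eff = np.where(t == "correct", beta_correct, np.where(t == "incorrect", beta_incorrect, 0.0))
        power = intercept + u + eff + noise_sd * rng.standard_normal(n_trials)
        for ttype, p in zip(t, power):
            rows.append({"animal_id": f"A{a + 1}", "trial_type": ttype, "power": p})
    return pd.DataFrame(rows)
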