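"""Attentional set-shifting behavioral scoring.

Mice dig in one of two pots whose compound stimuli combine an odor
(paprika or cinnamon) with a digging medium (corncob or paper). During
initial acquisition (IA) one dimension predicts reward; in the
extradimensional (ED) shift the rewarded dimension changes. A phase ends
when the animal is correct on 8 of 10 consecutive trials. ED errors are
perseverative when the chosen stimulus on the old (IA) rule's dimension is
the previously rewarded one, otherwise random; a trial lasting longer than
10 minutes is ended and scored as an error (classified random, since no
choice was made).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CRITERION_NEEDED = 8
CRITERION_WINDOW = 10
TIMEOUT_S = 600.0

ODORS = ("paprika", "cinnamon")
MEDIA = ("corncob", "paper")
DIMENSIONS = {"odor": ODORS, "medium": MEDIA}

#: Columns of the behavior CSV dialect.
BEHAVIOR_COLUMNS = [
    "trial_id",
    "phase",
    "chosen_odor",
    "chosen_medium",
    "correct",
    "latency_s",
    "timeout",
]


@dataclass(frozen=True)
class RuleSpec:
    """The rewarded stimulus within one dimension (e.g. odor=cinnamon)."""

    dimension: str
    rewarded_stimulus: str

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"dimension must be one of {sorted(DIMENSIONS)}")
        if self.rewarded_stimulus not in DIMENSIONS[self.dimension]:
            raise ValueError(
                f"{self.rewarded_stimulus!r} is not a {self.dimension} stimulus"
            )

    def chose_rewarded(self, row) -> bool:
        return row[f"chosen_{self.dimension}"] == self.rewarded_stimulus


@dataclass
class BehaviorSession:
    """Trial-by-trial log with the active rules.

    ``trials`` carries the columns of :data:`BEHAVIOR_COLUMNS`. The IA and
    ED rules must differ in dimension. ``censored`` marks a session whose
    ED phase hit the trial cap before reaching criterion.
    """

    trials: pd.DataFrame = field(repr=False)
    ia_rule: RuleSpec = RuleSpec("odor", "cinnamon")
    ed_rule: RuleSpec = RuleSpec("medium", "paper")
    censored: bool = False

    def __post_init__(self) -> None:
        if self.ia_rule.dimension == self.ed_rule.dimension:
            raise ValueError("IA and ED rules must differ in dimension")
        df = self.trials.reset_index(drop=True)
        missing = set(BEHAVIOR_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"behavior table missing columns: {sorted(missing)}")
        bad = df["timeout"].astype(bool) & df["correct"].astype(bool)
        if bad.any():
            raise ValueError("a timeout trial cannot be correct")
        self.trials = df

    def phase_trials(self, phase: str) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == phase]


@dataclass
class SessionScore:
    """Per-phase summary of a set-shifting session."""

    phase: str
    trials_to_criterion: int | None
    total_errors: int
    perseverative_errors: int | None = None
    random_errors: int | None = None
    perseverative_pct: float | None = None
    random_pct: float | None = None
    mean_latency: float = float("nan")
    censored: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def trials_to_criterion(
    outcomes, needed: int = CRITERION_NEEDED, window: int = CRITERION_WINDOW
) -> int | None:
    """Trials until ``needed`` of the last ``window`` trials are correct.

    Returns the 1-based index of the trial completing the first qualifying
    window (so the earliest possible value is ``window``), or ``None`` when
    the criterion is never met.
    """
    if needed > window:
        raise ValueError("needed cannot exceed window")
    y = np.asarray(list(outcomes), dtype=bool)
    if y.size == 0:
        raise ValueError("empty outcome sequence")
    for t in range(window, y.size + 1):
        if int(y[t - window : t].sum()) >= needed:
            return t
    return None


def classify_errors(ed_trials: pd.DataFrame, ia_rule: RuleSpec) -> tuple[int, int]:
    """Split ED errors into perseverative and random counts.

    An error is perseverative iff the chosen stimulus on the IA rule's
    dimension equals the IA-rewarded stimulus. Timeout errors are random:
    no choice was made.
    """
    errors = ed_trials[~ed_trials["correct"].astype(bool)]
    perseverative = 0
    random = 0
    col = f"chosen_{ia_rule.dimension}"
    for _, row in errors.iterrows():
        if row["timeout"]:
            random += 1
            continue
        choice = row[col]
        if pd.isna(choice) or choice == "":
            raise ValueError(
                f"trial {row['trial_id']}: error trial lacks a chosen {ia_rule.dimension}"
            )
        if choice == ia_rule.rewarded_stimulus:
            perseverative += 1
        else:
            random += 1
    return perseverative, random


def score_session(session: BehaviorSession) -> dict[str, SessionScore]:
    """Score both phases: criterion, errors, taxonomy (ED), latency.

    Latency averages over completed (non-timeout) trials. When a phase
    never reaches criterion the score is flagged censored and
    ``trials_to_criterion`` is None. Error percentages are None when there
    are no errors.
    """
    scores: dict[str, SessionScore] = {}
    for phase in ("IA", "ED"):
        df = session.phase_trials(phase)
        if df.empty:
            continue
        outcomes = df["correct"].astype(bool).to_numpy()
        ttc = trials_to_criterion(outcomes)
        total_errors = int((~outcomes).sum())
        completed = df[~df["timeout"].astype(bool)]
        mean_latency = float(completed["latency_s"].mean()) if len(completed) else float("nan")
        score = SessionScore(
            phase=phase,
            trials_to_criterion=ttc,
            total_errors=total_errors,
            mean_latency=mean_latency,
            censored=ttc is None,
        )
        if phase == "ED":
            p, r = classify_errors(df, session.ia_rule)
            score.perseverative_errors = p
            score.random_errors = r
            if total_errors > 0:
                score.perseverative_pct = 100.0 * p / total_errors
                score.random_pct = 100.0 * r / total_errors
        scores[phase] = score
    return scores


def read_behavior(path) -> pd.DataFrame:
    """Read a behavior trial log CSV, validating its columns."""
    df = pd.read_csv(path)
    missing = set(BEHAVIOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["correct"] = df["correct"].astype(bool)
    df["timeout"] = df["timeout"].astype(bool)
    return df


def write_behavior(trials: pd.DataFrame, path) -> None:
    trials[BEHAVIOR_COLUMNS].to_csv(path, index=False)
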