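"""Single-feature trial-outcome decoder with exact binomial significance.

The classifier is a linear rule on one scalar (choice-window band power):
any monotone linear model on a single feature reduces to a direction and a
threshold. Training uses a class-balanced random draw (five correct and
five incorrect trials); the model is then tested on every remaining trial
and its success count compared with a 50%-chance binomial by a one-sided
upper-tail exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import BandSpec

logger = logging.getLogger(__name__)


@dataclass
class DecoderModel:
    """Threshold rule on the scalar feature.

    Predicts "correct" when ``direction * feature > threshold``. If the
    training features were all identical the model is degenerate and
    predicts by a seeded coin flip.
    """

    direction: float
    threshold: float
    trained_on: np.ndarray = field(repr=False)
    degenerate: bool = False
    seed: int | None = None

    def predict(self, features: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if self.degenerate:
            if rng is None:
                rng = np.random.default_rng(self.seed)
            return rng.random(x.shape) < 0.5
        return self.direction * x > self.threshold


@dataclass
class DecoderResult:
    """Test-set evaluation: counts, accuracy, and binomial p-value."""

    n_test: int
    n_correct_pred: int
    accuracy: float
    p_value: float
    seed: int | None = None
    band: BandSpec | None = None

    def to_dict(self) -> dict:
        d = {
            "n_test": self.n_test,
            "n_correct_pred": self.n_correct_pred,
            "accuracy": self.accuracy,
            "p_value": self.p_value,
            "seed": self.seed,
        }
        if self.band is not None:
            d["band"] = {"lo": self.band.lo, "hi": self.band.hi, "label": self.band.label}
        return d


def feature_table(
    records: pd.DataFrame, band: str = "65hz", window: str = "choice"
) -> pd.DataFrame:
    """One row per trial with its scalar feature and outcome.

    All trials with a recorded outcome are kept regardless of the
    trial-duration exclusion: the decoder compares the choice window with
    nothing, so the overlap rule does not apply.
    """
    sub = records[
        (records["band"] == band)
        & (records["window"] == window)
        & (records["reason"] != "no_dig")
        & records["power"].notna()
    ]
    return (
        sub[["trial_id", "outcome", "power"]]
        .drop_duplicates("trial_id")
        .reset_index(drop=True)
    )


def split_balanced(
    trials: pd.DataFrame, n_per_class: int = 5, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-balanced random train split; everything else is the test set.

    Draws ``n_per_class`` correct and ``n_per_class`` incorrect trials
    without replacement. Raises (naming the deficient class) when a class
    has too few trials, or when no trials remain for testing.
    """
    rng = np.random.default_rng(seed)
    train_idx = []
    for outcome in ("correct", "incorrect"):
        idx = trials.index[trials["outcome"] == outcome].to_numpy()
        if idx.size < n_per_class:
            raise ValueError(
                f"need {n_per_class} {outcome} trials for training, got {idx.size}"
            )
        train_idx.append(rng.choice(idx, size=n_per_class, replace=False))
    train_idx = np.concatenate(train_idx)
    test = trials.drop(index=train_idx)
    if len(test) == 0:
        raise ValueError("no trials left to test after the training draw")
    return trials.loc[train_idx].reset_index(drop=True), test.reset_index(drop=True)


def fit(train: pd.DataFrame, seed: int | None = None) -> DecoderModel:
    """Fit the threshold rule on a balanced training set.

    Direction is the sign of (mean correct − mean incorrect) feature.
    The threshold maximizes training accuracy over the projected feature
    ``direction * x`` and sits at the midpoint of the optimal gap; among
    equally accurate thresholds the lowest is chosen.
    """
    x = train["power"].to_numpy(float)
    y = (train["outcome"] == "correct").to_numpy()
    if not y.any() or y.all():
        raise ValueError("training set must contain both outcomes")
    if np.ptp(x) == 0:
        logger.warning("all training features identical: degenerate coin-flip model")
        return DecoderModel(1.0, float(x[0]), train["trial_id"].to_numpy(), True, seed)
    direction = np.sign(x[y].mean() - x[~y].mean())
    if direction == 0:
        direction = 1.0
    z = direction * x
    order = np.unique(z)
    # candidate thresholds: below all values, between neighbours, above all
    mids = (order[:-1] + order[1:]) / 2.0
    candidates = np.concatenate(([order[0] - 1.0], mids, [order[-1] + 1.0]))
    acc = np.array([np.mean((z > c) == y) for c in candidates])
    best = candidates[np.argmax(acc)]  # first (lowest) maximizer
    return DecoderModel(float(direction), float(best), train["trial_id"].to_numpy(), False, seed)


def evaluate(model: DecoderModel, test: pd.DataFrame, band: BandSpec | None = None) -> DecoderResult:
    """Count exact outcome predictions on the test set."""
    if len(test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(test["power"].to_numpy(float))
    truth = (test["outcome"] == "correct").to_numpy()
    k = int(np.sum(pred == truth))
    n = len(test)
    return DecoderResult(n, k, k / n, binomial_pvalue(k, n), model.seed, band)


def binomial_pvalue(k: int, n: int, p0: float = 0.5) -> float:
    """One-sided upper-tail exact binomial probability P(X >= k).

    X ~ Binomial(n, p0): the chance of at least the observed number of
    successful predictions under chance-level accuracy.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n and n >= 1")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    return float(stats.binom.sf(k - 1, n, p0))


def decode(
    records: pd.DataFrame,
    band: BandSpec,
    n_per_class: int = 5,
    seed: int | None = None,
) -> DecoderResult:
    """Full decoding round: feature extraction, balanced split, fit, test."""
    trials = feature_table(records, band=band.label)
    train, test = split_balanced(trials, n_per_class=n_per_class, seed=seed)
    model = fit(train, seed=seed)
    return evaluate(model, test, band=band)


def repeated_decode(
    trials: pd.DataFrame,
    n_per_class: int = 5,
    n_repeats: int = 100,
    seed: int | None = None,
) -> list[DecoderResult]:
    """Stability study: repeat the random training draw ``n_repeats`` times.

    Off by default in the pipeline, whose primary analysis uses a single
    draw; useful for estimating the accuracy distribution over splits.
    ``trials`` is a feature table (one row per trial).
    """
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_repeats):
        s = int(child.generate_state(1)[0] % (2**31))
        train, test = split_balanced(trials, n_per_class=n_per_class, seed=s)
        model = fit(train, seed=s)
        out.append(evaluate(model, test))
    return out
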