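"""Group-level statistics: pooled t-tests, trial-level mixed models, power.

The behavioral group comparisons use the classical pooled-variance
(Student) unpaired t-test, which can be computed either from raw samples
or from published summaries (mean, SEM, n) — the two routes agree exactly
because the pooled statistic depends on the data only through those
summaries.

Trial-level 65-Hz band power is modelled with a linear mixed model:
power ~ trial type (baseline / correct / incorrect, baseline reference)
[+ group], with a random intercept per animal, fit by REML; contrasts are
tested by Wald z.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.power import TTestIndPower

logger = logging.getLogger(__name__)

TRIAL_TYPES = ("baseline", "correct", "incorrect")


@dataclass(frozen=True)
class SummaryStat:
    """Published group summary: mean ± SEM with group size."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.sem <= 0:
            raise ValueError("sem must be positive")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)

    @classmethod
    def from_samples(cls, x) -> "SummaryStat":
        x = np.asarray(x, dtype=float)
        return cls(float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size)), int(x.size))


@dataclass
class TestResult:
    """Statistic, degrees of freedom, p-value, and estimate with CI."""

    statistic: float
    df: float
    p: float
    estimate: float | None = None
    se: float | None = None
    ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "estimate": self.estimate,
            "se": self.se,
            "ci": list(self.ci) if self.ci is not None else None,
        }


def pooled_t_from_summary(a: SummaryStat, b: SummaryStat) -> TestResult:
    """Two-sample Student t-test with pooled variance from summaries.

    sd_i = sem_i * sqrt(n_i); s²_p = ((n_a−1)sd_a² + (n_b−1)sd_b²) /
    (n_a+n_b−2); t = (mean_a−mean_b) / (s_p sqrt(1/n_a+1/n_b)); two-sided p
    on n_a+n_b−2 degrees of freedom.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    diff = a.mean - b.mean
    t = diff / se
    p = 2 * sps.t.sf(abs(t), df)
    half = sps.t.ppf(0.975, df) * se
    return TestResult(float(t), float(df), float(p), float(diff), float(se), (diff - half, diff + half))


def unpaired_t(x, y) -> TestResult:
    """Pooled-variance t-test from raw samples (equals the summary route)."""
    return pooled_t_from_summary(SummaryStat.from_samples(x), SummaryStat.from_samples(y))


def lmm_table(records: pd.DataFrame, band: str = "65hz", group: str | None = None) -> pd.DataFrame:
    """Trial-level rows for the mixed model from a band-power table.

    Baseline-window power enters as trial type ``baseline``; choice-window
    power as the trial's outcome (``correct``/``incorrect``). Trials
    flagged excluded (latency ≤ 6 s, or no dig) are dropped — the
    baseline/choice comparison requires non-overlapping windows.
    """
    sub = records[(records["band"] == band) & (~records["excluded"])]
    rows = []
    for _, r in sub.iterrows():
        if r["window"] == "baseline":
            ttype = "baseline"
        elif r["window"] == "choice":
            ttype = r["outcome"]
        else:
            continue
        row = {"animal_id": r["animal_id"], "trial_type": ttype, "power": r["power"]}
        if group is not None:
            row["group"] = r[group] if group in sub.columns else group
        rows.append(row)
    return pd.DataFrame(rows)


def fit_power_lmm(
    table: pd.DataFrame, include_group: bool = False, alpha: float = 0.05
) -> dict[str, TestResult]:
    """Random-intercept mixed model for trial-level band power.

    ``table`` needs columns ``animal_id``, ``trial_type`` (baseline /
    correct / incorrect) and ``power`` (plus ``group`` when
    ``include_group``). Returns Wald-z results for the contrasts
    correct−baseline, incorrect−baseline, and correct−incorrect. A
    singular fit (zero between-animal variance) falls back to OLS with a
    logged warning.
    """
    df = table.copy()
    if df["animal_id"].nunique() < 2:
        raise ValueError("need at least 2 animals")
    present = df["trial_type"].unique()
    if len(present) < 2:
        raise ValueError("need at least 2 trial types")
    formula = "power ~ C(trial_type, Treatment('baseline'))"
    if include_group:
        formula += " + C(group)"

    params, cov, singular = None, None, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["animal_id"])
            fit = model.fit(reml=True)
            if not np.all(np.isfinite(fit.bse_fe)) or float(fit.cov_re.iloc[0, 0]) <= 1e-10:
                singular = True
            else:
                params = fit.fe_params
                cov = fit.cov_params().loc[params.index, params.index]
        except Exception:
            singular = True
    if singular:
        logger.warning("singular mixed-model fit: falling back to OLS")
        ols = smf.ols(formula, df).fit()
        params = ols.params
        cov = ols.cov_params()

    def name(level: str) -> str:
        return f"C(trial_type, Treatment('baseline'))[T.{level}]"

    z975 = sps.norm.ppf(1 - alpha / 2)

    def wald(vec: pd.Series) -> TestResult:
        est = float(vec @ params)
        se = float(np.sqrt(vec @ cov.values @ vec))
        z = est / se
        p = 2 * sps.norm.sf(abs(z))
        return TestResult(float(z), np.inf, float(p), est, se, (est - z975 * se, est + z975 * se))

    out: dict[str, TestResult] = {}
    idx = list(params.index)
    for level, key in (("correct", "correct_vs_baseline"), ("incorrect", "incorrect_vs_baseline")):
        if name(level) in idx:
            v = pd.Series(np.zeros(len(idx)), index=idx)
            v[name(level)] = 1.0
            out[key] = wald(v)
    if name("correct") in idx and name("incorrect") in idx:
        v = pd.Series(np.zeros(len(idx)), index=idx)
        v[name("correct")] = 1.0
        v[name("incorrect")] = -1.0
        out["correct_vs_incorrect"] = wald(v)
    return out


def required_n_per_group(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.8,
    alternative: str = "two-sided",
) -> int:
    """Smallest per-group n giving the target power for a two-sample t-test.

    The sidedness convention is configurable (``"two-sided"`` or
    ``"larger"``) and should be reported alongside the result; the choice
    moves the answer by one animal at large effect sizes.
    """
    if delta == 0:
        raise ValueError("delta must be nonzero")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if alternative not in ("two-sided", "larger"):
        raise ValueError("alternative must be 'two-sided' or 'larger'")
    solver = TTestIndPower()
    effect = abs(delta) / sd
    # direct upward scan: achieved power is monotone in n, and the smallest
    # admissible group size is 2 (otherwise df = 2n-2 vanishes)
    n = 2
    while solver.power(effect, n, alpha, alternative=alternative) < power:
        n += 1
        if n > 10_000_000:
            raise RuntimeError("no attainable sample size (effect too small)")
    return n
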