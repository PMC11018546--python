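"""Prognostic stratification by cohesion-score threshold sweep.

For one community, the cohort is split at every threshold t on a regular
grid over [0, 1] into a low-cohesion group (score < t) and a high-cohesion
group (score >= t); survival separation is evaluated with the two-group
log-rank test on follow-up truncated at a horizon (default 5 years, events
after the horizon treated as censored there).  The threshold minimizing
the log-rank p is reported together with the full grid.  The optimized p
is reported as-is — it is threshold-optimized and therefore optimistic,
which the output notes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)

__all__ = ["SweepResult", "logrank", "threshold_sweep", "load_survival"]


def load_survival(path) -> pd.DataFrame:
    """Read a survival TSV (sample_id, time, event) into an indexed frame."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("sample_id")
    return validate_survival(df)


def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids in survival table")
    time = df["time"].astype(float)
    event = df["event"].astype(int)
    if not np.isfinite(time).all() or (time <= 0).any():
        raise ValueError("follow-up times must be finite and positive")
    if not set(event.unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    return pd.DataFrame({"time": time, "event": event}, index=df.index)


def logrank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic and p-value."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    if int(group_a["event"].sum() + group_b["event"].sum()) == 0:
        raise ValueError("no events to compare")
    res = logrank_test(
        group_a["time"], group_b["time"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def _logrank_grid(time: np.ndarray, event: np.ndarray, in_a: np.ndarray) -> tuple[float, float]:
    """Vectorized two-group log-rank (standard Mantel-Haenszel form).

    Numerically identical to :func:`logrank`; used inside the threshold
    sweep where one lifelines call per grid split would dominate runtime.
    """
    from scipy.stats import chi2

    order = np.argsort(time, kind="stable")
    time, event, in_a = time[order], event[order], in_a[order]
    uniq, start = np.unique(time, return_index=True)
    n = time.size
    # at-risk counts just before each distinct time
    at_risk = n - start
    at_risk_a = in_a.sum() - np.concatenate(([0], np.cumsum(in_a)))[start]
    d = np.add.reduceat(event, start)
    d_a = np.add.reduceat(event * in_a, start)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected_a = d * at_risk_a / at_risk
        var = (
            d
            * (at_risk_a / at_risk)
            * (1.0 - at_risk_a / at_risk)
            * (at_risk - d)
            / np.maximum(at_risk - 1.0, 1.0)
        )
    observed_minus_expected = float(np.nansum(d_a - expected_a))
    v = float(np.nansum(var))
    if v == 0:
        return 0.0, 1.0
    stat = observed_minus_expected**2 / v
    return float(stat), float(chi2.sf(stat, 1))


@dataclass
class SweepResult:
    """Outcome of a threshold sweep for one community."""

    community: str
    best_threshold: float
    p_value: float
    n_low: int
    n_high: int
    grid: pd.DataFrame = field(repr=False)  # threshold, p_value, n_low, n_high

    def write(self, path) -> None:
        self.grid.to_csv(path, sep="\t", index=False)


def _truncate(survival: pd.DataFrame, horizon: float) -> pd.DataFrame:
    late = survival["time"] > horizon
    out = survival.copy()
    out.loc[late, "time"] = horizon
    out.loc[late, "event"] = 0
    return out


def threshold_sweep(
    scores: pd.Series,
    survival: pd.DataFrame,
    step: float = 0.001,
    min_group: int = 10,
    horizon: float | None = 5.0,
    community: str = "community",
) -> SweepResult:
    """Find the cohesion threshold with the most distinct survival split.

    ``scores`` maps sample id -> cohesion score for one community;
    ``survival`` holds time/event indexed by the same ids.  The grid is
    t = 0, step, 2*step, ..., floor(1/step)*step; splits leaving either
    group below ``min_group`` are inadmissible.  Ties on the minimum p go
    to the smaller threshold.  ``horizon=None`` disables truncation.
    """
    if not (0.0 < step < 1.0):
        raise ValueError("step must be in (0, 1)")
    if min_group < 1:
        raise ValueError("min_group must be >= 1")
    common = scores.index.intersection(survival.index)
    if len(common) < len(scores):
        logger.warning("%d scored samples lack survival data", len(scores) - len(common))
    scores = scores.loc[common].astype(float)
    survival = validate_survival(survival.loc[common])
    if horizon is not None:
        survival = _truncate(survival, horizon)
    if int(survival["event"].sum()) == 0:
        raise ValueError("no events to compare")

    order = np.argsort(scores.to_numpy(), kind="stable")
    sorted_scores = scores.to_numpy()[order]
    sorted_surv = survival.iloc[order]
    n = len(sorted_scores)

    n_thresholds = math.floor(1.0 / step) + 1
    thresholds = np.arange(n_thresholds) * step
    # thresholds inducing the same partition share one log-rank test
    cache: dict[int, tuple[float, float]] = {}
    rows = []
    for t in thresholds:
        n_low = int(np.searchsorted(sorted_scores, t, side="left"))
        n_high = n - n_low
        if n_low < min_group or n_high < min_group:
            rows.append((float(t), np.nan, n_low, n_high))
            continue
        if n_low not in cache:
            in_low = np.zeros(n, dtype=bool)
            in_low[:n_low] = True
            cache[n_low] = _logrank_grid(
                sorted_surv["time"].to_numpy(),
                sorted_surv["event"].to_numpy(float),
                in_low,
            )
        _, p = cache[n_low]
        rows.append((float(t), p, n_low, n_high))
    grid = pd.DataFrame(rows, columns=["threshold", "p_value", "n_low", "n_high"])
    admissible = grid.dropna(subset=["p_value"])
    if admissible.empty:
        raise ValueError("no valid threshold: every split is inadmissible")
    best = admissible.loc[admissible["p_value"].idxmin()]  # idxmin: first minimum
    return SweepResult(
        community=community,
        best_threshold=float(best["threshold"]),
        p_value=float(best["p_value"]),
        n_low=int(best["n_low"]),
        n_high=int(best["n_high"]),
        grid=grid,
    )
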