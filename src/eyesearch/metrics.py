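"""Summary statistics: set-size linear fits, slope ratios, and
predicted-vs-observed goodness-of-fit (r^2, aare, aae).

``aare`` (average absolute relative error) and ``aae`` (average absolute
error) complement r^2: r^2 measures pattern agreement, the error metrics
measure absolute agreement in the variable's own units. r^2 is defined as
the squared Pearson correlation between predicted and observed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import ConditionSummary, summaries_to_frame

#: Positive slopes smaller than this (ms/object) make the negative:positive
#: slope ratio meaningless (flat search functions).
SLOPE_RATIO_EPS = 2.0


@dataclass
class LinearFit:
    intercept: float
    slope: float
    r2: float


@dataclass
class FitMetrics:
    r2: float
    aare: float  # fraction, not percent
    aae: float  # units of the variable


@dataclass
class FitReport:
    rt: FitMetrics
    er: FitMetrics
    overall: FitMetrics


@dataclass
class SlopeRatio:
    value: float
    meaningful: bool


def linear_fit(set_sizes: Sequence[float], means: Sequence[float]) -> LinearFit:
    """Ordinary least squares of condition means over set size."""
    x = np.asarray(set_sizes, dtype=float)
    y = np.asarray(means, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 aligned (set_size, mean) pairs")
    if np.ptp(y) == 0.0:
        return LinearFit(intercept=float(y[0]), slope=0.0, r2=0.0)
    res = stats.linregress(x, y)
    return LinearFit(intercept=float(res.intercept), slope=float(res.slope),
                     r2=float(res.rvalue) ** 2)


def slope_ratio(neg: LinearFit, pos: LinearFit, eps: float = SLOPE_RATIO_EPS) -> SlopeRatio:
    """Negative-trial RT slope over positive-trial RT slope.

    Flagged as not meaningful when the positive slope is within ``eps`` of
    zero (essentially flat search functions, as in the Color task).
    """
    if abs(pos.slope) < eps:
        return SlopeRatio(value=float("nan"), meaningful=False)
    return SlopeRatio(value=neg.slope / pos.slope, meaningful=True)


def fit_metrics(pred: Sequence[float], obs: Sequence[float]) -> FitMetrics:
    """r^2, aare, and aae between aligned predicted and observed vectors.

    Zero-valued observations are excluded from aare (with a warning) since
    their relative error is undefined.
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.size < 1:
        raise ValueError("pred and obs must be aligned, non-empty vectors")
    abs_err = np.abs(p - o)
    aae = float(abs_err.mean())
    nonzero = o != 0.0
    if not nonzero.all():
        warnings.warn("zero-valued observations excluded from aare", stacklevel=2)
    aare = float((abs_err[nonzero] / np.abs(o[nonzero])).mean()) if nonzero.any() else float("nan")
    if p.size < 2 or np.ptp(p) == 0.0 or np.ptp(o) == 0.0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(p, o)[0, 1]) ** 2
    return FitMetrics(r2=r2, aare=aare, aae=aae)


OBSERVED_COLUMNS = ["task", "polarity", "set_size", "mean_rt_ms", "error_rate"]


def compare_to_observed(
    summaries: Iterable[ConditionSummary],
    observed,
) -> FitReport:
    """Goodness-of-fit of simulated condition means against observed means.

    ``observed`` is a DataFrame or a CSV path with columns
    ``task, polarity, set_size, mean_rt_ms, error_rate``. Cells are aligned
    by key, so row order is irrelevant; observed cells missing from the
    simulation (or vice versa) raise an error naming them.
    """
    pred = summaries_to_frame(summaries)
    obs = observed if isinstance(observed, pd.DataFrame) else pd.read_csv(observed)
    missing_cols = [c for c in OBSERVED_COLUMNS if c not in obs.columns]
    if missing_cols:
        raise ValueError(f"observed data missing columns {missing_cols}")

    key = ["task", "polarity", "set_size"]
    pred_keys = set(map(tuple, pred[key].itertuples(index=False)))
    obs_keys = set(map(tuple, obs[key].itertuples(index=False)))
    if pred_keys != obs_keys:
        missing = sorted(pred_keys ^ obs_keys)
        raise ValueError(f"unmatched design cells: {missing}")

    merged = pred.merge(obs, on=key, suffixes=("_pred", "_obs")).sort_values(key)
    rt = fit_metrics(merged["mean_rt_ms_pred"], merged["mean_rt_ms_obs"])
    er = fit_metrics(merged["error_rate_pred"], merged["error_rate_obs"])
    pooled_pred = np.concatenate([merged["mean_rt_ms_pred"], merged["error_rate_pred"]])
    pooled_obs = np.concatenate([merged["mean_rt_ms_obs"], merged["error_rate_obs"]])
    overall = fit_metrics(pooled_pred, pooled_obs)
    return FitReport(rt=rt, er=er, overall=overall)


def rt_fits_by_polarity(summaries: Iterable[ConditionSummary]) -> dict[str, LinearFit]:
    """Linear RT-vs-set-size fit per trial polarity."""
    df = summaries_to_frame(summaries)
    out = {}
    for pol, group in df.groupby("polarity"):
        g = group.sort_values("set_size")
        out[str(pol)] = linear_fit(g["set_size"].to_numpy(), g["mean_rt_ms"].to_numpy())
    return out
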