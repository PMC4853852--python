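"""Kaplan-Meier estimation, log-rank testing and KR-based sample grouping.

Validates candidate key regulators prognostically: a 1x2 self-organizing
map groups samples by their KR expression profiles under a Pearson
correlation distance, Kaplan-Meier curves and the log-rank test compare the
groups, and single-KR mean/median expression splits test each regulator on
its own. Group differences are called significant below a configurable
log-rank p threshold (default 0.075).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: default log-rank significance threshold for the KR survival validation.
SURVIVAL_P_THRESHOLD = 0.075


def _check_table(time: np.ndarray, event: np.ndarray) -> None:
    if len(time) == 0:
        raise ValueError("empty survival table")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (event)")


def km_estimate(time, event) -> pd.DataFrame:
    """Product-limit estimate of the survival function.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i,
    with d_i events among n_i at risk. Samples censored exactly at an event
    time count as at risk at that time (standard convention). Returns a
    step-function table with columns time, at_risk, events, censored,
    survival; S(0) = 1 and S is non-increasing.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_table(time, event)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    rows = [(0.0, len(time), 0, 0, 1.0)]
    s = 1.0
    for t in np.unique(time):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        c = int(((time == t) & (event == 0)).sum())
        if d > 0:
            s *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, c, s))
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "censored", "survival"])


def km_survival_at(curve: pd.DataFrame, t: float) -> float:
    """S(t) from a km_estimate table (right-continuous step function)."""
    below = curve[curve["time"] <= t]
    return float(below["survival"].iloc[-1]) if len(below) else 1.0


def median_survival(curve: pd.DataFrame) -> float:
    """Smallest time with S(t) <= 0.5, or NaN if the curve never drops there."""
    hit = curve[curve["survival"] <= 0.5]
    return float(hit["time"].iloc[0]) if len(hit) else float("nan")


@dataclass
class LogrankResult:
    chi2: float
    p: float
    observed1: float  # events in group 1
    expected1: float


def logrank_test(group_labels, time, event) -> LogrankResult:
    """Two-group log-rank test (1 df).

    At each distinct event time t with d_t events among n_t at risk
    (n_1t in group 1): E_1t = d_t n_1t / n_t and
    V_t = d_t (n_1t/n_t)(n_2t/n_t)(n_t - d_t)/(n_t - 1); times with
    n_t = 1 are skipped. chi2 = (O_1 - E_1)^2 / sum V_t, p from chi2(1).
    """
    g = np.asarray(group_labels)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_table(time, event)
    groups = np.unique(g)
    if len(groups) != 2:
        raise ValueError(f"exactly 2 non-empty groups required, got {len(groups)}")
    if event.sum() == 0:
        raise ValueError("no events observed")
    in1 = g == groups[0]
    O1 = E1 = V = 0.0
    for t in np.unique(time[event == 1]):
        at = time >= t
        n_t = int(at.sum())
        if n_t <= 1:
            continue
        d_t = int(((time == t) & (event == 1)).sum())
        n1 = int((at & in1).sum())
        d1 = int(((time == t) & (event == 1) & in1).sum())
        O1 += d1
        E1 += d_t * n1 / n_t
        V += d_t * (n1 / n_t) * ((n_t - n1) / n_t) * (n_t - d_t) / (n_t - 1)
    if V == 0:
        raise ValueError("zero log-rank variance (degenerate grouping)")
    chi2 = (O1 - E1) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(chi2=float(chi2), p=p, observed1=float(O1), expected1=float(E1))


def som_two_cluster(
    kr_expr: pd.DataFrame, seed: int = 0, n_iter: int = 100
) -> pd.Series:
    """1x2 self-organizing map over samples under a Pearson distance.

    ``kr_expr`` is samples x KRs. The two nodes are initialized from the
    two maximally distant samples (d = 1 - pearson), trained online with a
    learning rate decaying linearly from 0.5 to 0.01 over ``n_iter`` passes
    in seeded random sample order, and each sample is finally assigned to
    its nearest node. Deterministic under a fixed seed.
    """
    X = kr_expr.to_numpy(dtype=float)
    n, k = X.shape
    if n < 4:
        raise ValueError("SOM needs >= 4 samples")
    if k < 2:
        raise ValueError("SOM needs >= 2 KR expression columns")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = list(kr_expr.index[sd == 0])
        raise ValueError(f"constant sample profile(s) {bad}: Pearson distance undefined")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]

    def pearson_dist(a: np.ndarray, b: np.ndarray) -> float:
        if a.std() == 0 or b.std() == 0:
            return 1.0
        return 1.0 - float(np.corrcoef(a, b)[0, 1])

    D = 1.0 - np.corrcoef(Z)
    i, j = np.unravel_index(np.argmax(D), D.shape)
    w = [X[i].copy(), X[j].copy()]
    rng = np.random.default_rng(seed)
    for it in range(n_iter):
        lr = 0.5 + (0.01 - 0.5) * (it / max(n_iter - 1, 1))
        for s in rng.permutation(n):
            d0, d1 = pearson_dist(X[s], w[0]), pearson_dist(X[s], w[1])
            best = 0 if d0 <= d1 else 1
            w[best] += lr * (X[s] - w[best])
    labels = np.array(
        [0 if pearson_dist(X[s], w[0]) <= pearson_dist(X[s], w[1]) else 1 for s in range(n)]
    )
    return pd.Series(labels, index=kr_expr.index, name="som_cluster")


@dataclass
class KrSplitResult:
    kr_id: str
    split: str
    split_value: float
    chi2: float
    p: float
    significant: bool
    direction: int  # +1: high-expression group survives longer; -1: worse
    n_low: int
    n_high: int


def kr_split_survival(
    table: pd.DataFrame,
    kr_id: str,
    split: str = "median",
    p_threshold: float = SURVIVAL_P_THRESHOLD,
) -> KrSplitResult:
    """Log-rank comparison of low vs high expression of one KR.

    Groups are {expression <= split value} vs {> split value} with the split
    at the median (default) or mean. Direction is the sign of (median
    survival of the high group - low group); when either median is undefined
    the sign of the high group's (E - O) is used (positive = fewer events
    than expected = better survival).
    """
    if kr_id not in table.columns:
        raise ValueError(f"KR {kr_id!r} not in survival table")
    expr = table[kr_id].to_numpy(dtype=float)
    if np.all(expr == expr[0]):
        raise ValueError(f"degenerate split: constant expression for {kr_id}")
    if split == "median":
        cut = float(np.median(expr))
    elif split == "mean":
        cut = float(expr.mean())
    else:
        raise ValueError("split must be 'median' or 'mean'")
    high = expr > cut
    if high.all() or not high.any():
        raise ValueError(f"degenerate split: all samples on one side for {kr_id}")
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)
    res = logrank_test(np.where(high, "high", "low"), time, event)
    med_high = median_survival(km_estimate(time[high], event[high]))
    med_low = median_survival(km_estimate(time[~high], event[~high]))
    if np.isfinite(med_high) and np.isfinite(med_low) and med_high != med_low:
        direction = 1 if med_high > med_low else -1
    else:
        # logrank groups sorted: 'high' < 'low' lexically -> group1 = high
        direction = 1 if res.expected1 > res.observed1 else -1
    return KrSplitResult(
        kr_id=kr_id,
        split=split,
        split_value=cut,
        chi2=res.chi2,
        p=res.p,
        significant=res.p <= p_threshold,
        direction=direction,
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
    )
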