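"""Dynamic discrimination and calibration metrics for landmark risk models.

Both metrics evaluate predictions made at an origin ``s`` against outcomes
over the following ``w`` years.  The concordance index is the truncated
(dynamic) C-index: among comparable pairs - one member has an observed
event within the window, the other is known to survive longer - the
proportion where the earlier event carries the higher predicted risk, ties
counting one half.  The Brier score is the inverse-probability-of-censoring
weighted (IPCW) mean squared error of the predicted event probability at
``s + w``, with the censoring distribution estimated by Kaplan-Meier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError, UndefinedMetricError


@dataclass
class MetricResult:
    landmark_age: float
    offset: float
    c_index: float
    brier: float
    n_evaluated: int
    n_events: int


def _observed(event_ages, censor_ages, origin, window):
    """Observed time since origin (truncated at the window) and event flag."""
    event_ages = np.asarray(event_ages, dtype=float)
    censor_ages = np.asarray(censor_ages, dtype=float)
    ev = np.where(np.isnan(event_ages), np.inf, event_ages)
    t_abs = np.minimum(ev, censor_ages)
    if np.any(t_abs <= origin):
        raise InputError("all subjects must be at risk beyond the origin")
    delta = ev <= censor_ages
    t = t_abs - origin
    over = t > window
    t = np.minimum(t, window)
    delta = delta & ~over
    return t, delta


def dynamic_c_index(risks, event_ages, censor_ages,
                    origin: float, window: float) -> float:
    """Truncated concordance index of predicted risks at ``origin``."""
    risks = np.asarray(risks, dtype=float)
    if not np.all(np.isfinite(risks)):
        raise InputError("risks must be finite")
    t, delta = _observed(event_ages, censor_ages, origin, window)
    n = len(risks)
    # pair (i, j) comparable when i has an event and j is known to outlive i
    ti = t[:, None]
    longer = (t[None, :] > ti) | ((t[None, :] == ti) & ~delta[None, :])
    comparable = delta[:, None] & longer
    np.fill_diagonal(comparable, False)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise UndefinedMetricError("no comparable pairs in the window")
    ri = risks[:, None]
    conc = (ri > risks[None, :]) & comparable
    tied = (ri == risks[None, :]) & comparable
    return float((conc.sum() + 0.5 * tied.sum()) / n_pairs)


def _censoring_survival(t, delta):
    """Kaplan-Meier estimate of the censoring survival G(t)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=~delta)
    return kmf


def dynamic_brier(risks, event_ages, censor_ages,
                  origin: float, window: float) -> float:
    """IPCW Brier score of predicted event probabilities at ``origin + window``.

    Events within the window contribute ``(1 - p)^2 / G(T-)``; subjects still
    at risk at the window contribute ``p^2 / G(w)``; subjects censored within
    the window contribute zero (their weight is carried by the IPCW).
    """
    risks = np.asarray(risks, dtype=float)
    if not np.all(np.isfinite(risks)):
        raise InputError("risks must be finite")
    t, delta = _observed(event_ages, censor_ages, origin, window)
    kmf = _censoring_survival(t, delta)
    eps = 1e-9
    g_at_w = float(kmf.predict(window - eps))
    if g_at_w <= 0:
        raise UndefinedMetricError("censoring survival vanishes before the horizon")
    n = len(risks)
    score = np.zeros(n)
    is_event = delta & (t <= window)
    at_risk = t >= window
    if np.any(is_event):
        g_minus = np.asarray(kmf.predict(t[is_event] - eps), dtype=float)
        if np.any(g_minus <= 0):
            raise UndefinedMetricError("degenerate censoring distribution")
        score[is_event] = (1.0 - risks[is_event]) ** 2 / g_minus
    score[at_risk] = risks[at_risk] ** 2 / g_at_w
    return float(score.sum() / n)


def evaluate_landmark(risks_by_offset: pd.DataFrame, persons: pd.DataFrame,
                      landmark_age: float, window: float) -> pd.DataFrame:
    """C-index and Brier per offset for a person x offset risk table.

    NaN metrics (with a reason left to the caller's log) are recorded when a
    metric is undefined at an offset (e.g. no comparable pairs).
    """
    per = persons.set_index("person_id")
    rows = []
    for col in risks_by_offset.columns:
        s = landmark_age + int(col)
        risks = risks_by_offset[col].dropna()
        sub = per.loc[risks.index]
        at_risk = (sub["cvd_age"].fillna(np.inf) > s) & \
                  (sub["death_or_censor_age"] > s)
        risks, sub = risks[at_risk.to_numpy()], sub[at_risk.to_numpy()]
        ev = sub["cvd_age"].to_numpy(dtype=float)
        cz = sub["death_or_censor_age"].to_numpy(dtype=float)
        t, delta = _observed(ev, cz, s, window)
        res = {"landmark_age": landmark_age, "offset": int(col),
               "n_evaluated": int(len(risks)), "n_events": int(delta.sum())}
        try:
            res["c_index"] = dynamic_c_index(risks.to_numpy(), ev, cz, s, window)
        except UndefinedMetricError:
            res["c_index"] = np.nan
        try:
            res["brier"] = dynamic_brier(risks.to_numpy(), ev, cz, s, window)
        except UndefinedMetricError:
            res["brier"] = np.nan
        rows.append(res)
    return pd.DataFrame(rows, columns=["landmark_age", "offset", "c_index",
                                       "brier", "n_evaluated", "n_events"])
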