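"""Net-benefit of candidate risk-assessment schedules and its optimizer.

A schedule with interval ``f`` holds visits at ``La, La+f, La+2f, ...`` up
to the 10-year horizon.  Statins start at the first visit at or after the
predicted threshold-crossing time ``t*``; visits stop once statins start.
The net benefit of a schedule is

    NB = QALY * lambda - cost,
    QALY = EFLY_NS + u_s * EFLY_S,
    cost = c_s * EFLY_S + c_v * E[N],

where ``EFLY_NS`` integrates the statin-free survival curve from the
landmark to the initiation visit, ``EFLY_S`` integrates the statin-adjusted
survival ``S_S(t) = S_NS(tau)^(1-theta) * S_NS(t)^theta`` from initiation to
the horizon, and ``E[N]`` is the expected number of visits (the initiation
visit index for crossers, ``1 + horizon/f`` for never-crossers).  Both
integrals are evaluated exactly on the step grid of the Breslow baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError
from .params import NbParams
from .survival import StepSurvival

#: Relative tolerance at which two net-benefit values count as tied; ties
#: are broken toward the larger (less frequent) interval.
NB_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class Schedule:
    """Equally spaced visit schedule starting at the landmark age."""

    interval: float
    landmark: float
    visit_times: tuple[float, ...]


def make_schedule(f: float, la: float, horizon: float = 10.0) -> Schedule:
    """Visits at ``la + (v-1)*f`` for as long as they stay within the horizon."""
    if f <= 0:
        raise InputError("visit interval f must be > 0")
    n = int(np.floor(horizon / f + 1e-12)) + 1
    times = tuple(la + f * v for v in range(n))
    return Schedule(interval=float(f), landmark=float(la), visit_times=times)


def statin_visit(schedule: Schedule, t_star: float | None):
    """Index (1-based) and age of the first visit at or after ``t_star``.

    Returns ``None`` when ``t_star`` is None (never crosses) or when no
    scheduled visit falls at or after ``t_star``.
    """
    if t_star is None:
        return None
    if t_star < schedule.landmark:
        raise InputError("t_star cannot precede the landmark age")
    times = np.asarray(schedule.visit_times)
    idx = int(np.searchsorted(times, t_star, side="left"))
    if idx >= len(times):
        return None
    return idx + 1, float(times[idx])


def expected_visits(schedule: Schedule, k_star: int | None,
                    horizon: float = 10.0) -> float:
    """Expected number of risk assessments, including the baseline visit.

    Crossers are assessed up to the initiation visit (``E[N] = k*``);
    never-crossers follow the continuous formula ``1 + horizon/f`` (e.g.
    4.33 for a 3-yearly schedule over 10 years).
    """
    if k_star is not None:
        return float(k_star)
    return 1.0 + horizon / schedule.interval


def efly_ns(survival: StepSurvival, la: float, tau_k: float) -> float:
    """Statin-free event-free life years: integral of S_NS from ``la`` to
    the initiation visit."""
    if tau_k < la:
        raise InputError("tau_k must be >= the landmark age")
    return survival.integrate(la, tau_k)


def efly_s(survival: StepSurvival, theta: float, tau_k: float,
           la: float, horizon: float = 10.0) -> float:
    """On-statin event-free life years.

    Integrates ``S_S(t) = S_NS(tau_k)^(1-theta) * S_NS(t)^theta`` from the
    initiation visit to the horizon; exact on the step grid.  Returns 0 when
    nobody survives to initiation (``S_NS(tau_k) = 0``).
    """
    if not 0 < theta <= 1:
        raise InputError("theta must be in (0, 1]")
    if not la <= tau_k <= la + horizon:
        raise InputError("tau_k must lie within the horizon")
    s_tau = survival(tau_k)
    if s_tau <= 0.0:
        return 0.0
    return s_tau ** (1.0 - theta) * survival.integrate(tau_k, la + horizon, power=theta)


def net_benefit_value(efly_ns_val: float, efly_s_val: float,
                      e_visits: float, params: NbParams) -> tuple[float, float, float]:
    """``(qaly, cost, nb)`` from the event-free life-year components."""
    qaly = efly_ns_val + params.statin_utility * efly_s_val
    cost = params.statin_cost * efly_s_val + params.visit_cost * e_visits
    return qaly, cost, qaly * params.lambda_wtp - cost


@dataclass
class NbResult:
    """Per-person net-benefit evaluation across all candidate intervals."""

    person_id: object
    landmark: float
    per_interval: pd.DataFrame   # f, k_star, tau_k, e_visits, efly_ns, efly_s, qaly, cost, nb
    optimal_f: float | None
    special_case: str            # none | never_crosses | very_high_at_La


def _argmax_interval(per: pd.DataFrame) -> float:
    nb = per["nb"].to_numpy()
    tol = NB_TIE_RTOL * max(1.0, float(np.max(np.abs(nb))))
    best = nb.max()
    tied = per.loc[nb >= best - tol, "f"]
    return float(tied.max())


def schedule_components(survival: StepSurvival, t_star: float | None,
                        la: float, params: NbParams) -> pd.DataFrame:
    """EFLY and visit-count components for every candidate interval.

    These do not depend on the economic parameters (lambda, u_s, c_s, c_v),
    so sensitivity analyses can reuse them.
    """
    rows = []
    for f in params.intervals:
        sched = make_schedule(f, la, params.horizon)
        sv = statin_visit(sched, t_star)
        if sv is None:
            k_star, tau_k = None, None
            e_ns = survival.integrate(la, la + params.horizon)
            e_s = 0.0
        else:
            k_star, tau_k = sv
            e_ns = efly_ns(survival, la, tau_k)
            e_s = efly_s(survival, params.hazard_ratio, tau_k, la, params.horizon)
        rows.append({
            "f": float(f),
            "k_star": np.nan if k_star is None else float(k_star),
            "tau_k": np.nan if tau_k is None else float(tau_k),
            "e_visits": expected_visits(sched, k_star, params.horizon),
            "efly_ns": e_ns,
            "efly_s": e_s,
        })
    return pd.DataFrame(rows)


def optimize_schedule(profile, survival: StepSurvival,
                      params: NbParams) -> NbResult:
    """Evaluate NB for every interval and return the argmax.

    ``profile`` must expose ``person_id``, ``landmark_age``,
    ``crossing_time`` and ``category`` (see
    :class:`cvsched.landmark.RiskProfile`).  People already above the
    threshold at the landmark age are flagged ``very_high_at_La`` and not
    optimized - they should initiate statins immediately.  Ties in NB are
    broken toward the larger interval.
    """
    la = profile.landmark_age
    if profile.category == "very_high":
        return NbResult(profile.person_id, la, pd.DataFrame(), None,
                        "very_high_at_La")
    t_star = profile.crossing_time
    special = "none"
    if t_star is None or t_star >= la + params.horizon:
        t_star = None
        special = "never_crosses"
    per = schedule_components(survival, t_star, la, params)
    qaly, cost, nb = net_benefit_value(
        per["efly_ns"].to_numpy(), per["efly_s"].to_numpy(),
        per["e_visits"].to_numpy(), params)
    per["qaly"], per["cost"], per["nb"] = qaly, cost, nb
    return NbResult(profile.person_id, la, per, _argmax_interval(per), special)


def evaluate_components_table(components: pd.DataFrame,
                              params: NbParams) -> pd.DataFrame:
    """Attach qaly/cost/nb columns to a tidy per-person component table."""
    out = components.copy()
    qaly, cost, nb = net_benefit_value(
        out["efly_ns"].to_numpy(), out["efly_s"].to_numpy(),
        out["e_visits"].to_numpy(), params)
    out["qaly"], out["cost"], out["nb"] = qaly, cost, nb
    return out


def optimal_f_by_person(components: pd.DataFrame, params: NbParams) -> pd.Series:
    """Argmax interval per person from a tidy component table
    (columns person_id, f, efly_ns, efly_s, e_visits)."""
    nb_tab = evaluate_components_table(components, params)
    return nb_tab.groupby("person_id", sort=True).apply(
        _argmax_interval, include_groups=False)


def sensitivity_grid(components: pd.DataFrame,
                     grids: dict, base: NbParams) -> pd.DataFrame:
    """Optimal-interval proportions across one-at-a-time parameter grids.

    ``grids`` maps NbParams field names (``lambda_wtp``, ``statin_utility``,
    ``statin_cost``, ``visit_cost``, ``hazard_ratio`` is *not* allowed here
    because EFLY components depend on it) to value lists.  Returns one row
    per (parameter, value, interval) with the cohort proportion whose
    optimum is that interval.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise InputError("sensitivity grids must be non-empty")
    if "hazard_ratio" in grids:
        raise InputError(
            "hazard_ratio changes the EFLY components; recompute them instead")
    rows = []
    for param, values in grids.items():
        for value in values:
            opts = optimal_f_by_person(components, base.replace(**{param: value}))
            counts = opts.value_counts(normalize=True)
            for f in base.intervals:
                rows.append({
                    "parameter": param, "value": float(value), "f": float(f),
                    "proportion": float(counts.get(float(f), 0.0)),
                })
    return pd.DataFrame(rows)
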