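"""Landmark cohorts, Cox fits, 5-year risk profiles and threshold crossing.

At each landmark age ``La`` the analysis keeps people who are CVD-free,
alive and statin-free at ``La``.  A 10-year Cox model fitted at ``La``
supplies the statin-free survival curve used by the net-benefit integrals;
a sequence of 5-year Cox models fitted at each prediction time
``s in {La, La+1, ..., La+10}`` (on the sub-cohort still at risk at ``s``)
supplies the dynamic 5-year risk profile, whose first crossing of the 5%
threshold - linearly interpolated between adjacent years - is the predicted
statin-initiation time ``t*``.

Coefficients are estimated by partial likelihood (via lifelines); the
baseline cumulative hazard at covariates ``= 0`` is the Breslow step
estimator, which reduces to Nelson-Aalen when all coefficients are zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EstimationError, InputError
from .params import INDICATORS, classify_risk  # re-exported: classify_risk
from .survival import StepSurvival

__all__ = [
    "select_landmark_cohort", "select_sub_cohort", "known_covariates",
    "CoxFit", "fit_landmark_cox", "predict_risk", "predict_risk_frame",
    "survival_curve_ns", "crossing_time", "classify_risk", "RiskProfile",
    "build_risk_profiles",
]


# --------------------------------------------------------------------------
# cohort selection
# --------------------------------------------------------------------------

def select_landmark_cohort(persons: pd.DataFrame, la: float) -> np.ndarray:
    """Person ids enrolled, alive, CVD-free and statin-free at ``la``."""
    cvd = persons["cvd_age"]
    statin = persons["statin_start_age"]
    mask = (
        (persons["entry_age"] <= la)
        & (persons["death_or_censor_age"] > la)
        & (cvd.isna() | (cvd > la))
        & (statin.isna() | (statin > la))
    )
    return np.sort(persons.loc[mask, "person_id"].to_numpy())


def select_sub_cohort(persons: pd.DataFrame, la: float, s: float) -> np.ndarray:
    """Members of the landmark cohort still alive and CVD-free at ``s``."""
    base = set(select_landmark_cohort(persons, la))
    cvd = persons["cvd_age"]
    mask = (
        persons["person_id"].isin(base)
        & (persons["death_or_censor_age"] > s)
        & (cvd.isna() | (cvd > s))
    )
    return np.sort(persons.loc[mask, "person_id"].to_numpy())


def known_covariates(persons: pd.DataFrame, la: float,
                     townsend_levels: int | None = None) -> pd.DataFrame:
    """Landmark-age values of the known covariates.

    Binary medication/disease indicators evaluated at ``la`` (onset at or
    before ``la``) plus Townsend dummies with the lowest level as reference.
    These values are carried forward unchanged to later prediction times.
    """
    per = persons.set_index("person_id").sort_index()
    out = pd.DataFrame(index=per.index)
    for ind in INDICATORS:
        onset = per[f"{ind}_onset_age"]
        out[ind] = ((onset <= la) & onset.notna()).astype(float)
    levels = townsend_levels or int(per["townsend"].max())
    for lvl in range(2, levels + 1):
        out[f"townsend_{lvl}"] = (per["townsend"] == lvl).astype(float)
    return out


# --------------------------------------------------------------------------
# Cox fitting
# --------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A landmark Cox fit with its Breslow baseline at covariates = 0."""

    origin: float
    window: float
    coefficients: pd.Series
    coef_se: pd.Series
    baseline_times: np.ndarray       # time since origin, strictly increasing
    baseline_cumhaz: np.ndarray      # non-decreasing, 0 before first time
    n_fit: int
    n_events: int
    dropped: tuple[str, ...] = ()    # constant columns removed before fitting

    def cumhaz_at(self, t_rel) -> np.ndarray:
        """Step evaluation of the baseline cumulative hazard."""
        t = np.asarray(t_rel, dtype=float)
        if len(self.baseline_times) == 0:
            out = np.zeros_like(t)
        else:
            idx = np.searchsorted(self.baseline_times, t, side="right") - 1
            out = np.where(idx < 0, 0.0, self.baseline_cumhaz[np.clip(idx, 0, None)])
        return float(out) if out.ndim == 0 else out

    def linear_predictor(self, covariates) -> float:
        if isinstance(covariates, pd.Series):
            covariates = covariates.to_dict()
        try:
            return float(sum(self.coefficients[k] * covariates[k]
                             for k in self.coefficients.index))
        except KeyError as err:
            raise InputError(f"missing covariate {err} for risk prediction") from err

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.coefficients, "se": self.coef_se})

    def baseline_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_since_origin": self.baseline_times,
                             "cumhaz": self.baseline_cumhaz})


def _breslow_baseline(durations: np.ndarray, events: np.ndarray,
                      eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Breslow step estimator of the baseline cumulative hazard at x = 0.

    ``dLambda(t_j) = d_j / sum_{i at risk at t_j} exp(eta_i)``; with all
    ``eta = 0`` this is the Nelson-Aalen estimator.
    """
    order = np.argsort(durations, kind="mergesort")
    t = durations[order]
    d = events[order].astype(bool)
    w = np.exp(eta[order])
    # suffix sums of w give the risk-set mass at each sorted time
    suffix = np.cumsum(w[::-1])[::-1]
    times, starts = np.unique(t, return_index=True)
    denom = suffix[starts]
    d_counts = np.add.reduceat(d.astype(float), starts)
    keep = d_counts > 0
    jumps = d_counts[keep] / denom[keep]
    return times[keep], np.cumsum(jumps)


def fit_landmark_cox(
    persons: pd.DataFrame,
    covariates: pd.DataFrame,
    ids: Iterable,
    origin: float,
    window: float,
    *,
    penalizer: float = 0.0,
) -> CoxFit:
    """Fit a Cox model on time since ``origin`` with censoring at
    ``origin + window``.

    ``covariates`` is a person-indexed design frame (known indicators,
    Townsend dummies and/or BLUP forecasts).  Columns constant over the fit
    sample are dropped (and recorded) because they are not estimable.
    Raises :class:`EstimationError` when the window holds no events or the
    partial likelihood does not converge.
    """
    ids = np.asarray(sorted(set(ids)))
    if len(ids) == 0:
        raise InputError("empty id set for Cox fit")
    per = persons.set_index("person_id").loc[ids]
    end = origin + window
    cvd = per["cvd_age"].to_numpy(dtype=float)
    dco = per["death_or_censor_age"].to_numpy(dtype=float)
    event_age = np.where(np.isnan(cvd), np.inf, cvd)
    stop = np.minimum(np.minimum(event_age, dco), end)
    events = (event_age <= stop) & (event_age <= end)
    durations = stop - origin
    if durations.min() <= 0:
        raise InputError("all subjects must be at risk strictly after the origin")
    n_events = int(events.sum())
    if n_events == 0:
        raise EstimationError(
            f"no events in ({origin}, {origin + window}] for this cohort")

    X = covariates.loc[ids].astype(float)
    variances = X.var(axis=0, ddof=0)
    dropped = tuple(variances.index[variances <= 1e-12])
    X = X.drop(columns=list(dropped))

    if X.shape[1] == 0:
        coefs = pd.Series(dtype=float)
        se = pd.Series(dtype=float)
        eta = np.zeros(len(ids))
    else:
        from lifelines import CoxPHFitter
        from lifelines.exceptions import ConvergenceError

        df = X.copy()
        df["duration"] = durations
        df["event"] = events.astype(int)
        cph = CoxPHFitter(penalizer=penalizer)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="duration", event_col="event")
        except (ConvergenceError, Exception) as err:  # noqa: BLE001
            raise EstimationError(
                f"Cox fit failed at origin {origin} "
                f"({n_events} events, {len(ids)} subjects): {err}") from err
        coefs = cph.params_.copy()
        coefs.index = [c for c in X.columns]
        se = cph.standard_errors_.copy()
        se.index = list(X.columns)
        if not np.all(np.isfinite(coefs.to_numpy())):
            raise EstimationError(
                f"non-finite Cox coefficients at origin {origin} "
                "(possible separation / monotone likelihood)")
        eta = X.to_numpy() @ coefs.to_numpy()

    times, cumhaz = _breslow_baseline(durations, events, eta)
    return CoxFit(
        origin=float(origin), window=float(window),
        coefficients=coefs, coef_se=se,
        baseline_times=times, baseline_cumhaz=cumhaz,
        n_fit=int(len(ids)), n_events=n_events, dropped=dropped,
    )


def predict_risk(fit: CoxFit, covariates) -> float:
    """Event probability by the end of the fit window:
    ``1 - exp(-Lambda0(window) * exp(x'beta))``."""
    eta = fit.linear_predictor(covariates)
    lam = fit.cumhaz_at(fit.window)
    return float(1.0 - np.exp(-lam * np.exp(eta)))


def predict_risk_frame(fit: CoxFit, covariates: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`predict_risk` over a person-indexed design frame."""
    cols = list(fit.coefficients.index)
    missing = [c for c in cols if c not in covariates.columns]
    if missing:
        raise InputError(f"missing covariates {missing} for risk prediction")
    eta = covariates[cols].to_numpy(dtype=float) @ fit.coefficients.to_numpy() \
        if cols else np.zeros(len(covariates))
    lam = fit.cumhaz_at(fit.window)
    return pd.Series(1.0 - np.exp(-lam * np.exp(eta)), index=covariates.index)


def survival_curve_ns(fit: CoxFit, covariates) -> StepSurvival:
    """Statin-free survival ``S(t) = exp(-Lambda0(t) e^{x'beta})`` on the
    fit window, as a step function in absolute age."""
    eta = fit.linear_predictor(covariates)
    return StepSurvival.from_cumhaz(
        origin=fit.origin, end=fit.origin + fit.window,
        times=fit.origin + fit.baseline_times,
        cumhaz=fit.baseline_cumhaz, log_hr=eta,
    )


# --------------------------------------------------------------------------
# risk profiles and threshold crossing
# --------------------------------------------------------------------------

def crossing_time(ages: Sequence[float], risks: Sequence[float],
                  threshold: float = 0.05) -> tuple[float | None, bool]:
    """First time the risk profile exceeds ``threshold`` (strictly).

    Scans the available (non-NaN) prefix of ``risks``; when the first
    exceedance occurs at grid point ``s0``, the crossing time is the linear
    interpolation between ``s0 - 1`` grid step and ``s0``.  Returns
    ``(t_star, very_high)`` where ``very_high`` marks an exceedance already
    at the first grid point (t* equal to the landmark age).  ``(None, False)``
    when the profile never exceeds the threshold.  Risks exactly at the
    threshold do not count as exceedances.
    """
    ages = np.asarray(ages, dtype=float)
    risks = np.asarray(risks, dtype=float)
    if ages.shape != risks.shape or ages.ndim != 1 or len(ages) == 0:
        raise InputError("ages and risks must be equal-length 1-D sequences")
    if len(ages) > 1 and np.any(np.diff(ages) <= 0):
        raise InputError("ages must be strictly increasing")
    n_valid = len(risks)
    nan_pos = np.nonzero(np.isnan(risks))[0]
    if len(nan_pos):
        n_valid = int(nan_pos[0])  # profile truncated (death / event)
    if n_valid == 0:
        raise InputError("risk at the first grid point is required")
    prefix = risks[:n_valid]
    if not np.all(np.isfinite(prefix)):
        raise InputError("risks must be finite")
    if prefix[0] > threshold:
        return float(ages[0]), True
    above = np.nonzero(prefix > threshold)[0]
    if len(above) == 0:
        return None, False
    j = int(above[0])
    r0, r1 = prefix[j - 1], prefix[j]
    t = ages[j - 1] + (threshold - r0) / (r1 - r0) * (ages[j] - ages[j - 1])
    return float(t), False


@dataclass
class RiskProfile:
    """Dynamic 5-year risk profile of one person at one landmark age."""

    person_id: object
    landmark_age: float
    offsets: tuple[int, ...]
    risks: np.ndarray                 # NaN where the person left the sub-cohort
    crossing_time: float | None
    category: str

    @property
    def very_high(self) -> bool:
        return self.category == "very_high"


def build_risk_profiles(
    landmark_age: float,
    risks_by_offset: pd.DataFrame,
    threshold: float = 0.05,
) -> list[RiskProfile]:
    """Assemble per-person profiles from a person x offset risk table.

    ``risks_by_offset`` has person_id index and integer offset columns
    (0..10); NaN marks offsets at which the person had left the sub-cohort.
    The category is determined by the risk at offset 0.
    """
    offsets = tuple(int(c) for c in risks_by_offset.columns)
    ages = landmark_age + np.asarray(offsets, dtype=float)
    out = []
    for pid, row in risks_by_offset.iterrows():
        risks = row.to_numpy(dtype=float)
        t_star, very_high = crossing_time(ages, risks, threshold)
        category = classify_risk(float(risks[0]), threshold)
        out.append(RiskProfile(
            person_id=pid, landmark_age=float(landmark_age),
            offsets=offsets, risks=risks,
            crossing_time=t_star, category=category,
        ))
    return out
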