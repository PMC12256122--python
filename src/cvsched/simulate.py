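"""Synthetic EHR cohort generator.

Emulates the statistical structure of a primary-care CVD cohort: sparse,
irregular repeated measures of five longitudinal risk factors with a linear
mixed-model mean structure; monotone medication/disease indicators switched
on by exponential clocks; CVD event times from a proportional-hazards model
driven by each person's *noise-free* current covariate values; administrative
censoring at a fixed age (deaths are not modelled separately — they are
folded into administrative censoring, matching how the downstream analysis
treats death as censoring).

Output tables
-------------
``PersonTable`` (one row per person):
    person_id, entry_age, exit_age, cvd_event, cvd_age, death_or_censor_age,
    statin_start_age, townsend, practice_id, sex,
    and one ``<indicator>_onset_age`` column per indicator in
    :data:`cvsched.params.INDICATORS` (NaN = never while under observation).

``MeasurementTable`` (long format, one row per factor per visit):
    person_id, age, outcome, value, bpm, statin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .exceptions import InputError
from .params import INDICATORS, OUTCOMES, RANEF_NAMES, TrueParams

PERSON_COLUMNS = (
    ["person_id", "entry_age", "exit_age", "cvd_event", "cvd_age",
     "death_or_censor_age", "statin_start_age", "townsend", "practice_id", "sex"]
    + [f"{ind}_onset_age" for ind in INDICATORS]
)
MEASUREMENT_COLUMNS = ["person_id", "age", "outcome", "value", "bpm", "statin"]

_EVENT_GRID_STEP = 0.1  # years; hazard inversion grid resolution


def _ranef_transform(cov: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix via eigendecomposition (handles boundary)."""
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def true_longitudinal_values(
    params: TrueParams,
    ranef: pd.DataFrame,
    persons: pd.DataFrame,
    age: float | np.ndarray,
) -> pd.DataFrame:
    """Noise-free factor values at ``age`` for every person in ``ranef``.

    Includes the medication adjustments (blood-pressure medication on SBP,
    statins on total cholesterol) implied by the onset ages in ``persons``.
    Smoking is returned on its latent continuous scale.
    """
    idx = ranef.index
    per = persons.set_index("person_id").loc[idx]
    a = np.broadcast_to(np.asarray(age, dtype=float), (len(idx),))
    ac = a - params.ref_age
    out = {}
    for k, o in enumerate(OUTCOMES):
        val = (
            params.fixed_intercepts[o]
            + ranef[f"{o}_int"].to_numpy()
            + (params.fixed_slopes[o] + ranef[f"{o}_slope"].to_numpy()) * ac
        )
        if o == "sbp":
            on = per["bpm_onset_age"].to_numpy() <= a
            val = val + params.bpm_effect_on_sbp * on
        if o == "tchol":
            on = per["statin_start_age"].to_numpy() <= a
            val = val + params.statin_effect_on_tchol * on
        out[o] = val
    return pd.DataFrame(out, index=idx)


def simulate_cohort(
    params: TrueParams,
    n_persons: int,
    seed: int,
    return_truth: bool = False,
):
    """Simulate a cohort; same ``seed`` gives byte-identical tables.

    Returns ``(persons, measurements)`` or, with ``return_truth=True``,
    ``(persons, measurements, ranef)`` where ``ranef`` is the per-person
    10-vector of true random effects (rows indexed by person_id).
    """
    if n_persons < 1:
        raise InputError("n_persons must be >= 1")
    params.validate()
    rng = np.random.default_rng(seed)
    n = int(n_persons)
    lo, hi = params.entry_age_range
    admin = float(params.admin_censor_age)

    entry = rng.uniform(lo, hi, n)
    townsend = rng.integers(1, params.townsend_levels + 1, n)
    practice = rng.integers(0, params.n_practices, n)
    b = rng.standard_normal((n, len(RANEF_NAMES))) @ _ranef_transform(params.ranef_cov).T

    onset = {}
    for name in list(INDICATORS) + ["statin"]:
        rate = params.indicator_onset_rates.get(name, 0.0)
        if rate > 0:
            onset[name] = entry + rng.exponential(1.0 / rate, n)
        else:
            onset[name] = np.full(n, np.inf)

    # --- CVD event times: invert the cumulative hazard on an age grid -------
    grid = np.arange(lo, admin + _EVENT_GRID_STEP, _EVENT_GRID_STEP)
    ac = grid - params.ref_age
    eta = np.zeros((n, grid.size))
    cc = params.cox_coefs
    ref = params.cox_reference
    for k, o in enumerate(OUTCOMES):
        val = (
            params.fixed_intercepts[o]
            + b[:, 2 * k, None]
            + (params.fixed_slopes[o] + b[:, 2 * k + 1, None]) * ac[None, :]
        )
        if o == "sbp":
            val = val + params.bpm_effect_on_sbp * (onset["bpm"][:, None] <= grid[None, :])
        if o == "tchol":
            val = val + params.statin_effect_on_tchol * (onset["statin"][:, None] <= grid[None, :])
        eta += cc[o] * (val - ref[o])
    for name in INDICATORS:
        eta += cc.get(name, 0.0) * (onset[name][:, None] <= grid[None, :])
    eta += cc.get("townsend", 0.0) * (townsend[:, None] - 1)

    hazard = params.baseline_hazard_rate * np.exp(eta)
    hazard[grid[None, :] <= entry[:, None]] = 0.0  # at risk only after entry
    cumhaz = np.concatenate(
        [np.zeros((n, 1)), cumulative_trapezoid(hazard, grid, axis=1)], axis=1
    )
    e_draw = rng.exponential(1.0, n)
    cvd_age = np.full(n, np.nan)
    has_event = cumhaz[:, -1] >= e_draw
    idx_ev = np.argmax(cumhaz >= e_draw[:, None], axis=1)
    for i in np.nonzero(has_event)[0]:
        j = idx_ev[i]
        c0, c1 = cumhaz[i, j - 1], cumhaz[i, j]
        frac = 0.0 if c1 == c0 else (e_draw[i] - c0) / (c1 - c0)
        cvd_age[i] = grid[j - 1] + frac * (grid[j] - grid[j - 1])
    # the grid cell containing the entry age has partial hazard mass; keep
    # interpolated event ages strictly inside the observation window
    cvd_age = np.where(np.isnan(cvd_age), np.nan,
                       np.maximum(cvd_age, entry + 1e-9))

    dco = np.full(n, admin)
    exit_age = np.where(np.isnan(cvd_age), dco, np.minimum(cvd_age, dco))
    cvd_event = ~np.isnan(cvd_age)

    def _trim(x: np.ndarray) -> np.ndarray:
        return np.where(x <= exit_age, x, np.nan)

    persons = pd.DataFrame({
        "person_id": np.arange(n),
        "entry_age": entry,
        "exit_age": exit_age,
        "cvd_event": cvd_event,
        "cvd_age": cvd_age,
        "death_or_censor_age": dco,
        "statin_start_age": _trim(onset["statin"]),
        "townsend": townsend,
        "practice_id": practice,
        "sex": "all",
    })
    for ind in INDICATORS:
        persons[f"{ind}_onset_age"] = _trim(onset[ind])
    persons = persons[list(PERSON_COLUMNS)]

    # --- measurements: homogeneous visit process, all 5 factors per visit ---
    followup = exit_age - entry
    n_visits = rng.poisson(params.measurement_rate * followup)
    total = int(n_visits.sum())
    if total == 0:
        meas = pd.DataFrame(
            {c: pd.Series(dtype=t) for c, t in zip(
                MEASUREMENT_COLUMNS, [int, float, str, float, int, int])}
        )
    else:
        pid = np.repeat(np.arange(n), n_visits)
        u = rng.random(total)
        ages = entry[pid] + u * followup[pid]
        order = np.lexsort((ages, pid))
        pid, ages = pid[order], ages[order]
        acm = ages - params.ref_age
        bpm_flag = (onset["bpm"][pid] <= ages).astype(int)
        statin_flag = (onset["statin"][pid] <= ages).astype(int)
        rows = []
        noise = rng.standard_normal((len(OUTCOMES), total))
        for k, o in enumerate(OUTCOMES):
            val = (
                params.fixed_intercepts[o]
                + b[pid, 2 * k]
                + (params.fixed_slopes[o] + b[pid, 2 * k + 1]) * acm
                + params.resid_sd[o] * noise[k]
            )
            if o == "sbp":
                val = val + params.bpm_effect_on_sbp * bpm_flag
            if o == "tchol":
                val = val + params.statin_effect_on_tchol * statin_flag
            if o == "smoke" and params.smoke_record == "binary":
                val = (val >= 0.5).astype(float)
            rows.append(pd.DataFrame({
                "person_id": pid, "age": ages, "outcome": o, "value": val,
                "bpm": bpm_flag, "statin": statin_flag,
            }))
        meas = pd.concat(rows, ignore_index=True)
        meas = meas.sort_values(
            ["person_id", "age", "outcome"], kind="mergesort"
        ).reset_index(drop=True)

    if return_truth:
        ranef = pd.DataFrame(b, columns=list(RANEF_NAMES))
        ranef.index = pd.Index(np.arange(n), name="person_id")
        return persons, meas, ranef
    return persons, meas


# --- CSV round-trip ---------------------------------------------------------

def write_person_table(persons: pd.DataFrame, path) -> None:
    persons.to_csv(path, index=False)


def read_person_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["cvd_event"] = df["cvd_event"].astype(bool)
    return df


def write_measurement_table(measurements: pd.DataFrame, path) -> None:
    measurements.to_csv(path, index=False)


def read_measurement_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
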