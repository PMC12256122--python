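"""Five-outcome linear mixed model and past-only BLUP forecasting.

The model stacks the five longitudinal risk factors into a single response.
For a measurement of factor *o* on person *i* at (centered) age *a*:

    y = beta_int[o] + beta_slope[o] * a
        + beta_bpm * BPM   (SBP rows only)
        + beta_statin * STATIN   (TCHOL rows only)
        + b[i, o_int] + b[i, o_slope] * a + eps,

with ``b_i ~ MVN(0, Sigma)`` (10x10 unstructured) and independent residuals
whose variance is factor-specific.  Maximum likelihood is computed by an
ECM algorithm: given the variance parameters, beta is the exact GLS solution;
the E-step uses the Woodbury identity so every per-person operation is on
10x10 matrices; the M-step updates Sigma and the residual variances from the
posterior moments.  Sigma stays positive semi-definite by construction.

BLUPs condition only on measurements taken at or before the information age
(forecasts must not peek at the future), whereas the fit uses all
measurements of cohort members.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EstimationError, InputError
from .params import FE_NAMES, OUTCOMES, RANEF_NAMES

_P = len(FE_NAMES)       # 12 fixed effects
_Q = len(RANEF_NAMES)    # 10 random effects
_OUT_IDX = {o: k for k, o in enumerate(OUTCOMES)}
_SBP = _OUT_IDX["sbp"]
_TCHOL = _OUT_IDX["tchol"]


@dataclass
class LmemParams:
    """Fitted mixed-model parameters (ML)."""

    fixed_effects: pd.Series          # index FE_NAMES; NaN where aliased
    ranef_cov: np.ndarray             # (10, 10), order RANEF_NAMES
    resid_var: pd.Series              # per outcome
    age_center: float
    loglik: float
    fe_se: pd.Series = None
    n_iter: int = 0
    converged: bool = True
    aliased: tuple[str, ...] = ()

    def to_json(self, path) -> None:
        d = {
            "fixed_effects": {k: (None if not np.isfinite(v) else float(v))
                              for k, v in self.fixed_effects.items()},
            "ranef_cov": np.asarray(self.ranef_cov).tolist(),
            "resid_var": {k: float(v) for k, v in self.resid_var.items()},
            "age_center": self.age_center,
            "loglik": self.loglik,
            "fe_se": None if self.fe_se is None else
                     {k: (None if not np.isfinite(v) else float(v))
                      for k, v in self.fe_se.items()},
            "n_iter": self.n_iter,
            "converged": self.converged,
            "aliased": list(self.aliased),
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LmemParams":
        with open(path) as fh:
            d = json.load(fh)

        def _ser(m):
            if m is None:
                return None
            return pd.Series({k: (np.nan if v is None else v) for k, v in m.items()})

        return cls(
            fixed_effects=_ser(d["fixed_effects"]).reindex(list(FE_NAMES)),
            ranef_cov=np.asarray(d["ranef_cov"], dtype=float),
            resid_var=_ser(d["resid_var"]).reindex(list(OUTCOMES)),
            age_center=d["age_center"],
            loglik=d["loglik"],
            fe_se=_ser(d["fe_se"]),
            n_iter=d["n_iter"],
            converged=d["converged"],
            aliased=tuple(d["aliased"]),
        )


@dataclass
class BlupSet:
    """Past-only random-effect posterior mode and forecasts for one person."""

    person_id: object
    prediction_times: np.ndarray
    predicted: pd.DataFrame           # rows = times, columns = OUTCOMES
    n_past_obs: int
    ranef_mode: np.ndarray            # (10,)


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------

def _design(ages_c: np.ndarray, out_idx: np.ndarray,
            bpm: np.ndarray, statin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(ages_c)
    X = np.zeros((n, _P))
    Z = np.zeros((n, _Q))
    r = np.arange(n)
    X[r, out_idx] = 1.0
    X[r, len(OUTCOMES) + out_idx] = ages_c
    sbp_rows = out_idx == _SBP
    tch_rows = out_idx == _TCHOL
    X[sbp_rows, _P - 2] = bpm[sbp_rows]
    X[tch_rows, _P - 1] = statin[tch_rows]
    Z[r, 2 * out_idx] = 1.0
    Z[r, 2 * out_idx + 1] = ages_c
    return X, Z


def _prepare_rows(measurements: pd.DataFrame, ids, age_center: float):
    m = measurements[measurements["person_id"].isin(ids)]
    if len(m) == 0:
        raise InputError("no measurements for the requested cohort")
    out_idx = m["outcome"].map(_OUT_IDX)
    if out_idx.isna().any():
        bad = sorted(set(m.loc[out_idx.isna(), "outcome"]))
        raise InputError(f"unknown outcome names: {bad}")
    return (
        m["person_id"].to_numpy(),
        (m["age"].to_numpy(dtype=float) - age_center),
        out_idx.to_numpy(dtype=np.int64),
        m["bpm"].to_numpy(dtype=float),
        m["statin"].to_numpy(dtype=float),
        m["value"].to_numpy(dtype=float),
    )


class _Stacked:
    """Per-person data padded into equal-length buckets for batched linalg.

    Padded rows carry outcome index -1 and get weight zero, so they do not
    contribute to any weighted statistic.
    """

    def __init__(self, pid, ages_c, out_idx, bpm, statin, y):
        order = np.argsort(pid, kind="mergesort")
        pid, ages_c, out_idx, bpm, statin, y = (
            a[order] for a in (pid, ages_c, out_idx, bpm, statin, y))
        uniq, starts = np.unique(pid, return_index=True)
        bounds = np.append(starts, len(pid))
        lengths = np.diff(bounds)
        self.person_ids = uniq
        self.n_persons = len(uniq)
        self.n_rows = len(pid)
        self.buckets = []
        X_all, Z_all = _design(ages_c, out_idx, bpm, statin)
        by_len: dict[int, list[int]] = {}
        for j, L in enumerate(lengths):
            by_len.setdefault(int(L), []).append(j)
        for L, members in sorted(by_len.items()):
            m = len(members)
            Y = np.zeros((m, L))
            X = np.zeros((m, L, _P))
            Z = np.zeros((m, L, _Q))
            O = np.full((m, L), -1, dtype=np.int64)
            for row, j in enumerate(members):
                s, e = bounds[j], bounds[j + 1]
                Y[row] = y[s:e]
                X[row] = X_all[s:e]
                Z[row] = Z_all[s:e]
                O[row] = out_idx[s:e]
            self.buckets.append({"Y": Y, "X": X, "Z": Z, "O": O,
                                 "members": np.asarray(members)})
        # per-outcome row counts
        self.n_by_outcome = np.zeros(len(OUTCOMES))
        for k in range(len(OUTCOMES)):
            self.n_by_outcome[k] = sum(
                int((bk["O"] == k).sum()) for bk in self.buckets)


def _sigma_inv_logdet(sigma: np.ndarray):
    """Inverse and log-determinant with an eigenvalue floor (PSD boundary)."""
    w, v = np.linalg.eigh(sigma)
    floor = 1e-12 * max(1.0, float(w.max()))
    w = np.clip(w, floor, None)
    inv = (v / w) @ v.T
    return inv, float(np.sum(np.log(w)))


def _weights(O: np.ndarray, sig2: np.ndarray) -> np.ndarray:
    w = np.where(O >= 0, 1.0 / sig2[np.clip(O, 0, None)], 0.0)
    return w


def _em_pass(stacked: _Stacked, sigma: np.ndarray, sig2: np.ndarray,
             active: np.ndarray):
    """One ECM iteration at the given variance parameters.

    Returns (beta_full, sigma_new, sig2_new, loglik, XtVX_active).
    ``loglik`` is the marginal Gaussian log-likelihood at the GLS beta and the
    *current* variance parameters.
    """
    sinv, slogdet_sigma = _sigma_inv_logdet(sigma)
    pa = int(active.sum())
    XtVX = np.zeros((pa, pa))
    XtVy = np.zeros(pa)
    cache = []
    for bk in stacked.buckets:
        Y, X, Z, O = bk["Y"], bk["X"][:, :, active], bk["Z"], bk["O"]
        w = _weights(O, sig2)
        Zw = Z * w[:, :, None]
        Xw = X * w[:, :, None]
        ZtWZ = np.einsum("mli,mlj->mij", Zw, Z)
        A = sinv[None, :, :] + ZtWZ
        M = np.linalg.inv(A)
        XtWZ = np.einsum("mli,mlj->mij", Xw, Z)
        ZtWy = np.einsum("mli,ml->mi", Zw, Y)
        XtWy = np.einsum("mli,ml->mi", Xw, Y)
        XtWX = np.einsum("mli,mlj->mij", Xw, X)
        XtMZ = np.einsum("mpi,mij->mpj", XtWZ, M)
        XtVX += XtWX.sum(0) - np.einsum("mpj,mqj->pq", XtMZ, XtWZ)
        XtVy += XtWy.sum(0) - np.einsum("mpj,mj->p", XtMZ, ZtWy)
        sign, logdet_A = np.linalg.slogdet(A)
        cache.append({"M": M, "w": w, "logdet_A": float(logdet_A.sum())})
    try:
        beta_a = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError as err:
        raise EstimationError(f"singular fixed-effects system: {err}") from err
    if not np.all(np.isfinite(beta_a)):
        raise EstimationError("non-finite fixed-effects solution")

    beta = np.full(_P, np.nan)
    beta[active] = beta_a

    sigma_acc = np.zeros((_Q, _Q))
    ss = np.zeros(len(OUTCOMES))
    quad = 0.0
    logdet_terms = 0.0
    for bk, ch in zip(stacked.buckets, cache):
        Y, X, Z, O = bk["Y"], bk["X"][:, :, active], bk["Z"], bk["O"]
        w, M = ch["w"], ch["M"]
        r = Y - np.einsum("mlp,p->ml", X, beta_a)
        Zw = Z * w[:, :, None]
        ZtWr = np.einsum("mli,ml->mi", Zw, r)
        b = np.einsum("mij,mj->mi", M, ZtWr)
        sigma_acc += np.einsum("mi,mj->ij", b, b) + M.sum(0)
        e = r - np.einsum("mli,mi->ml", Z, b)
        q = np.einsum("mli,mij,mlj->ml", Z, M, Z)
        contrib = e * e + q
        for k in range(len(OUTCOMES)):
            mask = O == k
            if mask.any():
                ss[k] += contrib[mask].sum()
        quad += float((w * r * r).sum() - np.einsum("mi,mij,mj->", ZtWr, M, ZtWr))
        logdet_terms += ch["logdet_A"]
    n_pers = stacked.n_persons
    nk = stacked.n_by_outcome
    loglik = -0.5 * (
        float(np.sum(nk * np.log(2 * np.pi * sig2)))
        + n_pers * slogdet_sigma
        + logdet_terms
        + quad
    )
    sigma_new = sigma_acc / n_pers
    sigma_new = 0.5 * (sigma_new + sigma_new.T)
    sig2_new = np.where(nk > 0, ss / np.maximum(nk, 1), sig2)
    return beta, sigma_new, sig2_new, loglik, XtVX


def fit_lmem(
    measurements: pd.DataFrame,
    persons: pd.DataFrame,
    cohort_ids: Iterable,
    age_center: float,
    *,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> LmemParams:
    """Fit the stacked five-outcome mixed model by ML (ECM algorithm).

    Uses *all* measurements of cohort members, past and future relative to
    the landmark: the fit estimates population parameters, while forecasting
    (:func:`compute_blups`) conditions on the past only.  Design columns that
    are identically zero (e.g. the statin adjustment when nobody is on
    statins) are reported in ``aliased`` with a NaN coefficient.
    """
    ids = pd.Index(sorted(set(cohort_ids)))
    if len(ids) == 0:
        raise InputError("empty cohort")
    pid, ages_c, out_idx, bpm, statin, y = _prepare_rows(measurements, ids, age_center)
    stacked = _Stacked(pid, ages_c, out_idx, bpm, statin, y)

    # columns with no support are aliased (zero design column)
    col_max = np.zeros(_P)
    for bk in stacked.buckets:
        col_max = np.maximum(col_max, np.abs(bk["X"]).max(axis=(0, 1)))
    active = col_max > 1e-12
    aliased = tuple(n for n, a in zip(FE_NAMES, active) if not a)

    # --- initial values: pooled OLS, split residual variance ----------------
    XtX = np.zeros((int(active.sum()),) * 2)
    Xty = np.zeros(int(active.sum()))
    for bk in stacked.buckets:
        X = bk["X"][:, :, active]
        mask = (bk["O"] >= 0).astype(float)
        Xm = X * mask[:, :, None]
        XtX += np.einsum("mli,mlj->ij", Xm, X)
        Xty += np.einsum("mli,ml->i", Xm, bk["Y"])
    try:
        beta0 = np.linalg.solve(XtX, Xty)
    except np.linalg.LinAlgError as err:
        raise EstimationError(f"rank-deficient fixed-effect design: {err}") from err
    v0 = np.zeros(len(OUTCOMES))
    age_ms = np.zeros(len(OUTCOMES))
    for bk in stacked.buckets:
        r = bk["Y"] - np.einsum("mlp,p->ml", bk["X"][:, :, active], beta0)
        for k in range(len(OUTCOMES)):
            mask = bk["O"] == k
            if mask.any():
                v0[k] += (r[mask] ** 2).sum()
                age_ms[k] += (bk["Z"][:, :, 2 * k + 1][mask] ** 2).sum()
    nk = np.maximum(stacked.n_by_outcome, 1)
    v0 = np.maximum(v0 / nk, 1e-12)
    age_ms = np.maximum(age_ms / nk, 1.0)
    sig2 = 0.6 * v0
    sigma = np.zeros((_Q, _Q))
    for k in range(len(OUTCOMES)):
        sigma[2 * k, 2 * k] = 0.4 * v0[k]
        sigma[2 * k + 1, 2 * k + 1] = 0.4 * v0[k] / age_ms[k]

    beta = np.full(_P, np.nan)
    loglik_prev = -np.inf
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        beta, sigma, sig2, loglik, XtVX = _em_pass(stacked, sigma, sig2, active)
        if np.isfinite(loglik_prev) and abs(loglik - loglik_prev) < tol * (1 + abs(loglik)):
            converged = True
            break
        loglik_prev = loglik

    # one last pass at the converged variance parameters for SEs / loglik
    beta, _, _, loglik, XtVX = _em_pass(stacked, sigma, sig2, active)
    try:
        fe_cov = np.linalg.inv(XtVX)
    except np.linalg.LinAlgError as err:
        raise EstimationError(f"singular information matrix: {err}") from err
    se = np.full(_P, np.nan)
    se[active] = np.sqrt(np.clip(np.diag(fe_cov), 0, None))

    return LmemParams(
        fixed_effects=pd.Series(beta, index=list(FE_NAMES)),
        ranef_cov=sigma,
        resid_var=pd.Series(sig2, index=list(OUTCOMES)),
        age_center=float(age_center),
        loglik=float(loglik),
        fe_se=pd.Series(se, index=list(FE_NAMES)),
        n_iter=it,
        converged=converged,
        aliased=aliased,
    )


# --------------------------------------------------------------------------
# BLUP forecasting
# --------------------------------------------------------------------------

def _fixed_effect_vector(params: LmemParams) -> np.ndarray:
    beta = params.fixed_effects.reindex(list(FE_NAMES)).to_numpy(dtype=float)
    return beta


def _mean_at(params: LmemParams, times_c: np.ndarray,
             bpm_status: bool, statin_status: bool) -> np.ndarray:
    """Fixed-effects mean per outcome at the (centered) prediction times."""
    beta = _fixed_effect_vector(params)
    K = len(OUTCOMES)
    mu = np.empty((len(times_c), K))
    for k in range(K):
        mu[:, k] = beta[k] + beta[K + k] * times_c
    if bpm_status:
        coef = beta[_P - 2]
        if not np.isfinite(coef):
            raise InputError("bpm adjustment requested but coefficient is aliased")
        mu[:, _SBP] += coef
    if statin_status:
        coef = beta[_P - 1]
        if not np.isfinite(coef):
            raise InputError("statin adjustment requested but coefficient is aliased")
        mu[:, _TCHOL] += coef
    return mu


def compute_blups(
    params: LmemParams,
    measurements: pd.DataFrame,
    person_id,
    information_age: float,
    prediction_times: Sequence[float],
    bpm_status: bool,
    statin_status: bool,
) -> BlupSet:
    """Posterior-mode random effects given the past, and forecasts.

    Only measurements with age <= ``information_age`` inform the posterior
    (``b = Sigma Z' V^{-1} (y - X beta)`` with ``V = Z Sigma Z' + R``); a
    person with no past measurements gets the population-mean trajectory.
    The prediction at each age is the fixed-effects mean under the supplied
    medication statuses plus the person's intercept/slope deviation, hence it
    is exactly affine in age.
    """
    times = np.asarray(prediction_times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise InputError("prediction_times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) <= 0) and len(times) > 1:
        raise InputError("prediction_times must be strictly increasing")
    if np.any(times < information_age):
        raise InputError("prediction times must be >= information_age")

    m = measurements[(measurements["person_id"] == person_id)
                     & (measurements["age"] <= information_age)]
    return _blup_from_rows(params, m, person_id, information_age, times,
                           bpm_status, statin_status)


def _blup_from_rows(params, m, person_id, information_age, times,
                    bpm_status, statin_status) -> BlupSet:
    b = np.zeros(_Q)
    if len(m) > 0:
        out_idx = m["outcome"].map(_OUT_IDX).to_numpy(dtype=np.int64)
        ages_c = m["age"].to_numpy(dtype=float) - params.age_center
        X, Z = _design(ages_c, out_idx,
                       m["bpm"].to_numpy(dtype=float),
                       m["statin"].to_numpy(dtype=float))
        beta = _fixed_effect_vector(params)
        usable = np.isfinite(beta)
        if np.any(~usable & (np.abs(X).max(axis=0) > 0)):
            bad = [n for n, u, c in zip(FE_NAMES, usable, np.abs(X).max(axis=0) > 0)
                   if not u and c]
            raise InputError(f"measurements load on aliased coefficients: {bad}")
        r = m["value"].to_numpy(dtype=float) - X[:, usable] @ beta[usable]
        R = np.diag(params.resid_var.reindex(list(OUTCOMES)).to_numpy()[out_idx])
        V = Z @ params.ranef_cov @ Z.T + R
        b = params.ranef_cov @ Z.T @ np.linalg.solve(V, r)

    times_c = times - params.age_center
    mu = _mean_at(params, times_c, bpm_status, statin_status)
    K = len(OUTCOMES)
    pred = mu + np.column_stack(
        [b[2 * k] + b[2 * k + 1] * times_c for k in range(K)]
    )
    return BlupSet(
        person_id=person_id,
        prediction_times=times,
        predicted=pd.DataFrame(pred, index=pd.Index(times, name="age"),
                               columns=list(OUTCOMES)),
        n_past_obs=int(len(m)),
        ranef_mode=np.asarray(b, dtype=float),
    )


def compute_blups_cohort(
    params: LmemParams,
    measurements: pd.DataFrame,
    persons: pd.DataFrame,
    ids: Iterable,
    information_age: float,
    prediction_times: Sequence[float],
    statin_status: bool = False,
) -> dict:
    """BLUPs for every person in ``ids`` at the same information age.

    Blood-pressure-medication status is carried forward from the landmark
    (onset at or before ``information_age``); statin status defaults to 0
    because landmark cohorts are statin-free at the landmark age.
    """
    times = np.asarray(prediction_times, dtype=float)
    per = persons.set_index("person_id")
    past = measurements[measurements["age"] <= information_age]
    groups = dict(tuple(past.groupby("person_id", sort=False)))
    empty = past.iloc[0:0]
    out = {}
    for pid in sorted(set(ids)):
        onset = per.at[pid, "bpm_onset_age"]
        bpm_status = bool(np.isfinite(onset) and onset <= information_age)
        out[pid] = _blup_from_rows(
            params, groups.get(pid, empty), pid, information_age, times,
            bpm_status=bpm_status, statin_status=statin_status,
        )
    return out


def blup_frame(blups: Mapping, s: float) -> pd.DataFrame:
    """Assemble the 5 forecast covariates at time ``s`` into a design frame.

    Columns are ``{outcome}_hat``; rows indexed by person_id.
    """
    rows = {}
    for pid, bs in blups.items():
        if s not in bs.predicted.index:
            raise InputError(f"time {s} not in the BLUP prediction grid of person {pid}")
        rows[pid] = bs.predicted.loc[s]
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"{o}_hat" for o in df.columns]
    df.index.name = "person_id"
    return df.sort_index()
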