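"""Parameter containers: simulator truth, landmark grid, and net-benefit economics.

Conventions
-----------
* The five longitudinal risk factors are always ordered
  ``("smoke", "hdl", "sbp", "tchol", "bmi")``; random effects are the
  interleaved per-factor (intercept, slope) pairs, giving a 10-vector.
* Fixed intercepts are expressed at the simulator reference age
  (``TrueParams.ref_age``), i.e. they are the population mean of each factor
  at that age, which keeps the numbers on a clinically readable scale.
* Monetary values are GBP; ages, durations and slopes are in years.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ParameterError

#: Longitudinal risk factors, in canonical order.
OUTCOMES: tuple[str, ...] = ("smoke", "hdl", "sbp", "tchol", "bmi")

#: Monotone medication / disease indicators (statin handled separately because
#: it defines cohort eligibility).
INDICATORS: tuple[str, ...] = (
    "diabetes", "renal", "depression", "migraine", "smi", "ra", "af", "bpm",
)

#: Names of the 10 random effects (intercept+slope per factor).
RANEF_NAMES: tuple[str, ...] = tuple(
    f"{o}_{kind}" for o in OUTCOMES for kind in ("int", "slope")
)

#: Names of the fixed effects of the multivariate mixed model.
FE_NAMES: tuple[str, ...] = (
    tuple(f"{o}_int" for o in OUTCOMES)
    + tuple(f"{o}_slope" for o in OUTCOMES)
    + ("sbp_bpm", "tchol_statin")
)

#: Risk categories from least to most severe.
CATEGORIES: tuple[str, ...] = ("low", "med_low", "med_high", "high", "very_high")


def _check_psd(mat: np.ndarray, name: str, tol: float = 1e-8) -> None:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (len(RANEF_NAMES), len(RANEF_NAMES)):
        raise ParameterError(f"{name} must be {len(RANEF_NAMES)}x{len(RANEF_NAMES)}")
    if not np.allclose(mat, mat.T, atol=1e-10 * (1 + np.abs(mat).max())):
        raise ParameterError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol * max(1.0, w.max()):
        raise ParameterError(f"{name} must be positive semi-definite (min eig {w.min():.3g})")


@dataclass
class TrueParams:
    """Generative ('true') parameters of the synthetic EHR cohort.

    ``fixed_intercepts`` are the factor means at ``ref_age``; each factor then
    drifts linearly with age.  ``ranef_cov`` is the 10x10 covariance of the
    per-person intercept/slope deviations (ordered as :data:`RANEF_NAMES`,
    intercepts expressed at ``ref_age``).  The CVD hazard is proportional:
    a constant baseline rate times ``exp`` of a linear predictor built from
    the *noise-free* current factor values (centered at ``cox_reference``),
    the current indicator states and the Townsend level.
    """

    fixed_intercepts: dict[str, float]
    fixed_slopes: dict[str, float]
    bpm_effect_on_sbp: float
    statin_effect_on_tchol: float
    ranef_cov: np.ndarray
    resid_sd: dict[str, float]
    cox_coefs: dict[str, float]
    baseline_hazard_rate: float
    measurement_rate: float
    indicator_onset_rates: dict[str, float]
    cox_reference: dict[str, float] | None = None
    townsend_levels: int = 5
    entry_age_range: tuple[float, float] = (35.0, 70.0)
    admin_censor_age: float = 80.0
    ref_age: float = 60.0
    n_practices: int = 20
    #: "binary": record smoke dichotomized at 0.5 (EHR-like); "latent": record
    #: the underlying continuous value (used by parameter-recovery checks).
    smoke_record: str = "binary"

    def __post_init__(self) -> None:
        self.ranef_cov = np.asarray(self.ranef_cov, dtype=float)
        if self.cox_reference is None:
            self.cox_reference = dict(self.fixed_intercepts)

    def validate(self) -> None:
        _check_psd(self.ranef_cov, "ranef_cov")
        for o in OUTCOMES:
            if self.resid_sd[o] <= 0:
                raise ParameterError(f"resid_sd[{o}] must be > 0")
        for name, rate in self.indicator_onset_rates.items():
            if rate < 0:
                raise ParameterError(f"indicator_onset_rates[{name}] must be >= 0")
        if self.baseline_hazard_rate < 0 or self.measurement_rate < 0:
            raise ParameterError("rates must be >= 0")
        if self.townsend_levels < 2:
            raise ParameterError("townsend_levels must be >= 2")
        lo, hi = self.entry_age_range
        if not lo < hi <= self.admin_censor_age:
            raise ParameterError("entry_age_range must be increasing and end before admin_censor_age")
        if self.smoke_record not in ("binary", "latent"):
            raise ParameterError("smoke_record must be 'binary' or 'latent'")

    # -- flat serialization (YAML/JSON-friendly) -----------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ranef_cov"] = self.ranef_cov.tolist()
        d["entry_age_range"] = list(self.entry_age_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrueParams":
        d = dict(d)
        d["ranef_cov"] = np.asarray(d["ranef_cov"], dtype=float)
        d["entry_age_range"] = tuple(d["entry_age_range"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TrueParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def replace(self, **kw) -> "TrueParams":
        return dataclasses.replace(self, **kw)


def _default_ranef_cov() -> np.ndarray:
    """Handcrafted PSD covariance with mildly correlated factors.

    Within-factor intercept/slope correlation is negative (regression to the
    mean); adiposity-related intercepts (SBP, TCHOL, BMI) are positively
    correlated, HDL negatively with BMI.
    """
    sd_int = {"smoke": 0.45, "hdl": 0.33, "sbp": 13.0, "tchol": 0.95, "bmi": 4.2}
    sd_slope = {"smoke": 0.012, "hdl": 0.006, "sbp": 0.45, "tchol": 0.035, "bmi": 0.12}
    sd = np.array(
        [v for o in OUTCOMES for v in (sd_int[o], sd_slope[o])], dtype=float
    )
    corr = np.eye(len(RANEF_NAMES))

    def set_corr(a: str, b: str, r: float) -> None:
        i, j = RANEF_NAMES.index(a), RANEF_NAMES.index(b)
        corr[i, j] = corr[j, i] = r

    for o in OUTCOMES:
        set_corr(f"{o}_int", f"{o}_slope", -0.25)
    set_corr("sbp_int", "bmi_int", 0.25)
    set_corr("tchol_int", "bmi_int", 0.20)
    set_corr("sbp_int", "tchol_int", 0.15)
    set_corr("hdl_int", "bmi_int", -0.25)
    set_corr("hdl_int", "tchol_int", 0.10)
    set_corr("smoke_int", "hdl_int", -0.10)
    set_corr("smoke_int", "tchol_int", 0.10)
    return corr * np.outer(sd, sd)


def default_true_params() -> TrueParams:
    """Documented, deterministic default generative parameters.

    Magnitudes follow typical UK primary-care populations: SBP around
    130 mmHg at age 60 rising ~0.45 mmHg/year, total cholesterol ~5.6 mmol/L
    lowered ~1.1 mmol/L on statins, blood-pressure medication lowering
    measured SBP ~9 mmHg.  The baseline CVD hazard is set so that the
    simulated 10-year incidence in the age-60 landmark cohort lands in the
    mid-single digits (checked by simulation in the test-suite).
    """
    return TrueParams(
        fixed_intercepts={"smoke": 0.32, "hdl": 1.45, "sbp": 132.0, "tchol": 5.6, "bmi": 27.2},
        fixed_slopes={"smoke": -0.004, "hdl": 0.002, "sbp": 0.45, "tchol": 0.012, "bmi": 0.05},
        bpm_effect_on_sbp=-9.0,
        statin_effect_on_tchol=-1.1,
        ranef_cov=_default_ranef_cov(),
        resid_sd={"smoke": 0.28, "hdl": 0.16, "sbp": 10.5, "tchol": 0.5, "bmi": 1.4},
        cox_coefs={
            "smoke": 0.38, "hdl": -0.45, "sbp": 0.018, "tchol": 0.16, "bmi": 0.02,
            "diabetes": 0.55, "renal": 0.35, "depression": 0.12, "migraine": 0.10,
            "smi": 0.25, "ra": 0.20, "af": 0.60, "bpm": 0.15,
            "townsend": 0.04,  # per level above the reference level
        },
        baseline_hazard_rate=0.0075,
        measurement_rate=0.4,
        indicator_onset_rates={
            "diabetes": 0.006, "renal": 0.003, "depression": 0.010, "migraine": 0.004,
            "smi": 0.002, "ra": 0.002, "af": 0.004, "bpm": 0.020, "statin": 0.012,
        },
    )


@dataclass(frozen=True)
class LandmarkSpec:
    """Landmark grid, horizon, risk window and initiation threshold."""

    landmark_ages: tuple[float, ...] = tuple(range(40, 85, 5))
    horizon: float = 10.0
    risk_window: float = 5.0
    threshold: float = 0.05
    prediction_offsets: tuple[int, ...] = tuple(range(11))

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ParameterError("threshold must be in (0,1)")
        if self.risk_window > self.horizon:
            raise ParameterError("risk_window must be <= horizon")


@dataclass(frozen=True)
class NbParams:
    """Economic parameters of the net-benefit function.

    ``lambda_wtp`` is the willingness-to-pay per quality-adjusted life year,
    ``statin_utility`` the utility weight of on-statin time (pill burden),
    ``hazard_ratio`` the multiplicative CVD hazard reduction on statins.
    """

    lambda_wtp: float = 25_000.0
    statin_utility: float = 0.997
    statin_cost: float = 150.0
    visit_cost: float = 18.39
    hazard_ratio: float = 0.8
    horizon: float = 10.0
    intervals: tuple[float, ...] = tuple(range(1, 11))

    def __post_init__(self) -> None:
        if not 0 < self.hazard_ratio <= 1:
            raise ParameterError("hazard_ratio must be in (0,1]")
        if not 0 < self.statin_utility <= 1:
            raise ParameterError("statin_utility must be in (0,1]")
        if min(self.statin_cost, self.visit_cost) < 0:
            raise ParameterError("costs must be >= 0")

    def replace(self, **kw) -> "NbParams":
        return dataclasses.replace(self, **kw)


def classify_risk(risk: float, threshold: float = 0.05) -> str:
    """Risk category from the 5-year risk at the landmark age.

    Half-open intervals, upper boundary inclusive: very_high > 5%,
    high in (3.75%, 5%], med_high in (2.5%, 3.75%], med_low in (1.25%, 2.5%],
    low <= 1.25%.  Cut-points scale with ``threshold`` (default 5%).
    """
    from .exceptions import InputError

    if not np.isfinite(risk) or not 0 <= risk <= 1:
        raise InputError(f"risk must lie in [0,1], got {risk!r}")
    cuts = (threshold, 0.75 * threshold, 0.5 * threshold, 0.25 * threshold)
    if risk > cuts[0]:
        return "very_high"
    if risk > cuts[1]:
        return "high"
    if risk > cuts[2]:
        return "med_high"
    if risk > cuts[3]:
        return "med_low"
    return "low"
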