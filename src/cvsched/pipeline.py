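"""End-to-end orchestration: simulate -> fit -> predict -> optimize -> report.

A run is configured by :class:`RunConfig` (YAML-loadable), executes stage by
stage into a run directory, and is fully reproducible: rerunning with the
same config and seed regenerates identical artifacts.  Stages reuse
artifacts already present in the run directory (person tables, fitted
mixed-model parameters), which is what the CLI stage subcommands rely on.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import landmark as lm
from . import netbenefit as nb
from . import validate as val
from .exceptions import InputError
from .lmem import LmemParams, blup_frame, compute_blups_cohort, fit_lmem
from .params import CATEGORIES, LandmarkSpec, NbParams, TrueParams, default_true_params
from .simulate import (read_measurement_table, read_person_table, simulate_cohort,
                       write_measurement_table, write_person_table)

logger = logging.getLogger("cvsched")

STAGES = ("simulate", "lmem", "cox", "profile", "optimize", "validate", "report")


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    seed: int = 0
    n_persons: int = 2000
    true_params: TrueParams = field(default_factory=default_true_params)
    spec: LandmarkSpec = field(default_factory=lambda: LandmarkSpec(landmark_ages=(60.0,)))
    nb: NbParams = field(default_factory=NbParams)
    sens_grids: dict = field(default_factory=lambda: {
        "lambda_wtp": [20_000.0, 25_000.0, 30_000.0],
        "statin_cost": [4.3, 150.0, 321.2],
    })
    outdir: str = "cvsched_run"
    validation_fraction: float = 1 / 3
    cox_penalizer: float = 0.0
    lmem_max_iter: int = 300
    lmem_tol: float = 1e-8

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        if "true_params" in raw:
            tp = default_true_params().to_dict()
            tp.update(raw.pop("true_params"))
            kw["true_params"] = TrueParams.from_dict(tp)
        if "spec" in raw:
            sp = raw.pop("spec")
            if "landmark_ages" in sp:
                sp["landmark_ages"] = tuple(float(a) for a in sp["landmark_ages"])
            if "prediction_offsets" in sp:
                sp["prediction_offsets"] = tuple(int(o) for o in sp["prediction_offsets"])
            kw["spec"] = LandmarkSpec(**sp)
        if "nb" in raw:
            nb_kw = raw.pop("nb")
            if "intervals" in nb_kw:
                nb_kw["intervals"] = tuple(float(f) for f in nb_kw["intervals"])
            kw["nb"] = NbParams(**nb_kw)
        kw.update(raw)
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_params"] = self.true_params.to_dict()
        d["spec"] = dataclasses.asdict(self.spec)
        d["spec"]["landmark_ages"] = list(self.spec.landmark_ages)
        d["spec"]["prediction_offsets"] = list(self.spec.prediction_offsets)
        d["nb"] = dataclasses.asdict(self.nb)
        d["nb"]["intervals"] = list(self.nb.intervals)
        return d


def split_by_practice(persons: pd.DataFrame, validation_fraction: float):
    """Deterministic derivation/validation split by practice id.

    The highest-numbered ``ceil(fraction * n_practices)`` practices form the
    validation set (mirrors a cluster-level held-out split).
    """
    practices = np.sort(persons["practice_id"].unique())
    n_val = int(np.ceil(validation_fraction * len(practices)))
    val_practices = set(practices[len(practices) - n_val:]) if n_val else set()
    is_val = persons["practice_id"].isin(val_practices)
    return (persons.loc[~is_val, "person_id"].to_numpy(),
            persons.loc[is_val, "person_id"].to_numpy())


@dataclass
class LandmarkResult:
    """All per-landmark artifacts of one analysis pass."""

    landmark_age: float
    lmem: LmemParams
    fit10: lm.CoxFit
    subfits: dict
    risks_by_offset: pd.DataFrame
    profiles: list
    survivals: dict
    nb_table: pd.DataFrame
    optima: pd.DataFrame
    components: pd.DataFrame


def run_landmark_analysis(
    persons: pd.DataFrame,
    measurements: pd.DataFrame,
    la: float,
    spec: LandmarkSpec,
    nb_params: NbParams,
    fit_ids=None,
    *,
    lmem: LmemParams | None = None,
    cox_penalizer: float = 0.0,
    lmem_max_iter: int = 300,
    lmem_tol: float = 1e-8,
) -> LandmarkResult:
    """Run the full two-stage landmark analysis at one landmark age.

    ``fit_ids`` restricts fitting (and net-benefit evaluation) to a subset,
    e.g. the derivation practices; default is everyone eligible.
    """
    cohort = lm.select_landmark_cohort(persons, la)
    if fit_ids is not None:
        cohort = np.intersect1d(cohort, np.asarray(fit_ids))
    if len(cohort) == 0:
        raise InputError(f"empty landmark cohort at age {la}")
    logger.info("landmark %s: cohort size %d", la, len(cohort))

    if lmem is None:
        lmem = fit_lmem(measurements, persons, cohort, age_center=la,
                        max_iter=lmem_max_iter, tol=lmem_tol)
        logger.info("landmark %s: LMEM loglik %.2f after %d iterations",
                    la, lmem.loglik, lmem.n_iter)

    pred_times = la + np.asarray(spec.prediction_offsets, dtype=float)
    blups = compute_blups_cohort(lmem, measurements, persons, cohort, la, pred_times)
    known = lm.known_covariates(persons, la)

    design0 = known.loc[cohort].join(blup_frame(blups, la))
    fit10 = lm.fit_landmark_cox(persons, design0, cohort, la, spec.horizon,
                                penalizer=cox_penalizer)
    logger.info("landmark %s: 10y fit on %d subjects, %d events",
                la, fit10.n_fit, fit10.n_events)

    subfits = {}
    risk_cols = {}
    for off in spec.prediction_offsets:
        s = la + off
        ids_s = np.intersect1d(lm.select_sub_cohort(persons, la, s), cohort)
        design_s = known.loc[ids_s].join(blup_frame(blups, s).loc[ids_s])
        fit_s = lm.fit_landmark_cox(persons, design_s, ids_s, s, spec.risk_window,
                                    penalizer=cox_penalizer)
        subfits[off] = fit_s
        risk_cols[off] = lm.predict_risk_frame(fit_s, design_s)
    risks_by_offset = pd.DataFrame(risk_cols).reindex(cohort)
    risks_by_offset.index.name = "person_id"

    profiles = lm.build_risk_profiles(la, risks_by_offset, spec.threshold)
    survivals = {pid: lm.survival_curve_ns(fit10, design0.loc[pid])
                 for pid in cohort}

    nb_rows, opt_rows, comp_rows = [], [], []
    for prof in profiles:
        res = nb.optimize_schedule(prof, survivals[prof.person_id], nb_params)
        opt_rows.append({
            "person_id": prof.person_id,
            "landmark": la,
            "category": prof.category,
            "t_star": np.nan if prof.crossing_time is None else prof.crossing_time,
            "optimal_f": np.nan if res.optimal_f is None else res.optimal_f,
            "special_case": res.special_case,
        })
        if res.special_case == "very_high_at_La":
            continue
        tab = res.per_interval.copy()
        tab.insert(0, "person_id", prof.person_id)
        tab.insert(1, "landmark", la)
        nb_rows.append(tab)
        comp = tab[["person_id", "f", "e_visits", "efly_ns", "efly_s"]]
        comp_rows.append(comp)
    nb_table = pd.concat(nb_rows, ignore_index=True) if nb_rows else pd.DataFrame()
    components = pd.concat(comp_rows, ignore_index=True) if comp_rows else pd.DataFrame()
    optima = pd.DataFrame(opt_rows)

    return LandmarkResult(
        landmark_age=la, lmem=lmem, fit10=fit10, subfits=subfits,
        risks_by_offset=risks_by_offset, profiles=profiles,
        survivals=survivals, nb_table=nb_table, optima=optima,
        components=components,
    )


def report_table1(optima: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Cross-tabulation of optimal interval by risk category.

    Returns ``(table, n_very_high)``: counts per interval and category among
    people not at very high risk, with row totals, row percentages and a
    column-total row; the very-high count is reported separately.
    """
    if len(optima) == 0:
        raise InputError("no net-benefit results to report")
    very_high = int((optima["special_case"] == "very_high_at_La").sum())
    body = optima[optima["special_case"] != "very_high_at_La"]
    cats = [c for c in ("high", "med_high", "med_low", "low")
            if c in set(body["category"])]
    tab = pd.crosstab(body["optimal_f"], body["category"])
    tab = tab.reindex(columns=cats, fill_value=0)
    tab["total"] = tab.sum(axis=1)
    grand = tab["total"].sum()
    tab["pct"] = 100.0 * tab["total"] / grand
    totals = tab.drop(columns="pct").sum(axis=0)
    totals["pct"] = 100.0
    tab.loc["total"] = totals
    tab.index.name = "optimal_f"
    return tab, very_high


# --------------------------------------------------------------------------
# staged pipeline
# --------------------------------------------------------------------------

def _stage_index(name: str) -> int:
    if name not in STAGES:
        raise InputError(f"unknown stage {name!r}; one of {STAGES}")
    return STAGES.index(name)


def run_pipeline(config: RunConfig, until: str = "report") -> Path:
    """Execute the pipeline into ``config.outdir`` up to stage ``until``.

    Existing person/measurement tables and fitted LMEM parameters in the run
    directory are reused, so stage subcommands can build on earlier runs.
    Returns the run directory path.
    """
    upto = _stage_index(until)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    p_path, m_path = out / "persons.csv", out / "measurements.csv"
    if p_path.exists() and m_path.exists():
        logger.info("reusing existing cohort tables in %s", out)
        persons = read_person_table(p_path)
        measurements = read_measurement_table(m_path)
    else:
        persons, measurements = simulate_cohort(
            config.true_params, config.n_persons, config.seed)
        write_person_table(persons, p_path)
        write_measurement_table(measurements, m_path)
        logger.info("simulated %d persons, %d measurement rows",
                    len(persons), len(measurements))
    cfg_echo = config.to_dict()
    cfg_echo.pop("outdir", None)  # the log lives in the run directory already
    run_log = {"config": cfg_echo, "landmarks": {}}
    if upto >= _stage_index("report"):
        pass  # run_log written at the end regardless
    if upto == 0:
        _write_log(out, run_log)
        return out

    deriv_ids, val_ids = split_by_practice(persons, config.validation_fraction)

    for la in config.spec.landmark_ages:
        tag = f"La{int(la)}"
        lmem_path = out / f"lmem_{tag}.json"
        lmem = LmemParams.from_json(lmem_path) if lmem_path.exists() else None
        if lmem is not None:
            logger.info("reusing fitted LMEM %s", lmem_path)
        result = None
        cohort = np.intersect1d(lm.select_landmark_cohort(persons, la), deriv_ids)
        if lmem is None:
            lmem = fit_lmem(measurements, persons, cohort, age_center=la,
                            max_iter=config.lmem_max_iter, tol=config.lmem_tol)
            lmem.to_json(lmem_path)
        run_log["landmarks"][int(la)] = {"cohort_size": int(len(cohort))}
        if upto < _stage_index("cox"):
            continue

        result = run_landmark_analysis(
            persons, measurements, la, config.spec, config.nb,
            fit_ids=deriv_ids, lmem=lmem, cox_penalizer=config.cox_penalizer,
        )
        run_log["landmarks"][int(la)].update({
            "n_events_10y": int(result.fit10.n_events),
            "sub_cohort_sizes": {int(off): int(f.n_fit)
                                 for off, f in result.subfits.items()},
        })
        coef_rows, base_rows = [], []
        for label, fit in [("h10", result.fit10)] + [
                (f"s{off}", f) for off, f in result.subfits.items()]:
            cf = fit.coef_frame().reset_index(names="covariate")
            cf.insert(0, "fit", label)
            coef_rows.append(cf)
            bf = fit.baseline_frame()
            bf.insert(0, "fit", label)
            base_rows.append(bf)
        pd.concat(coef_rows, ignore_index=True).to_csv(
            out / f"cox_{tag}_coefs.csv", index=False)
        pd.concat(base_rows, ignore_index=True).to_csv(
            out / f"cox_{tag}_baseline.csv", index=False)
        if upto < _stage_index("profile"):
            continue

        tidy = result.risks_by_offset.reset_index().melt(
            id_vars="person_id", var_name="offset", value_name="risk")
        meta = result.optima[["person_id", "t_star", "category"]]
        tidy = tidy.merge(meta, on="person_id", how="left")
        tidy.insert(1, "landmark", la)
        tidy.sort_values(["person_id", "offset"]).to_csv(
            out / f"risk_profiles_{tag}.csv", index=False)
        if upto < _stage_index("optimize"):
            continue

        nb_out = result.nb_table.merge(
            result.optima[["person_id", "optimal_f", "special_case", "category"]],
            on="person_id", how="left")
        nb_out.to_csv(out / f"nb_results_{tag}.csv", index=False)
        result.optima.to_csv(out / f"nb_optima_{tag}.csv", index=False)
        if len(result.components):
            sens = nb.sensitivity_grid(result.components, config.sens_grids,
                                       config.nb)
            sens.to_csv(out / f"sensitivity_{tag}.csv", index=False)
        if upto < _stage_index("validate"):
            continue

        if config.validation_fraction > 0 and len(val_ids):
            metrics = _validate_landmark(
                persons, measurements, la, config, result.lmem,
                result.subfits, val_ids)
            metrics.to_csv(out / f"validation_{tag}.csv", index=False)
            run_log["landmarks"][int(la)]["validation_n"] = int(
                len(np.intersect1d(lm.select_landmark_cohort(persons, la), val_ids)))
        else:
            logger.info("validation skipped (no held-out practices)")
        if upto < _stage_index("report"):
            continue

        table1, n_vh = report_table1(result.optima)
        table1.to_csv(out / f"table1_{tag}.csv")
        run_log["landmarks"][int(la)]["very_high_excluded"] = n_vh

    _write_log(out, run_log)
    return out


def _validate_landmark(persons, measurements, la, config, lmem,
                       subfits, val_ids) -> pd.DataFrame:
    """Held-out risk predictions and dynamic metrics at one landmark."""
    spec = config.spec
    cohort = np.intersect1d(lm.select_landmark_cohort(persons, la),
                            np.asarray(val_ids))
    if len(cohort) == 0:
        return pd.DataFrame(columns=["landmark_age", "offset", "c_index",
                                     "brier", "n_evaluated", "n_events"])
    pred_times = la + np.asarray(spec.prediction_offsets, dtype=float)
    blups = compute_blups_cohort(lmem, measurements, persons, cohort, la, pred_times)
    known = lm.known_covariates(persons, la)
    risk_cols = {}
    for off, fit in subfits.items():
        s = la + off
        ids_s = np.intersect1d(lm.select_sub_cohort(persons, la, s), cohort)
        if len(ids_s) == 0:
            continue
        design_s = known.loc[ids_s].join(blup_frame(blups, s).loc[ids_s])
        risk_cols[off] = lm.predict_risk_frame(fit, design_s)
    risks = pd.DataFrame(risk_cols).reindex(cohort)
    return val.evaluate_landmark(risks, persons, la, spec.risk_window)


def _write_log(out: Path, run_log: dict) -> None:
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(run_log, fh, sort_keys=True)
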