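"""Shared fixtures: simulated cohorts and fitted landmark analyses.

The heavier artifacts (a mid-size landmark analysis and a large
parameter-recovery fit) are session-scoped so several test modules can
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import cvsched as cs
from cvsched.params import LandmarkSpec, NbParams


@pytest.fixture(scope="session")
def default_params():
    return cs.default_true_params()


@pytest.fixture(scope="session")
def small_cohort(default_params):
    """A small cohort for cheap structural checks."""
    persons, meas = cs.simulate_cohort(default_params, 300, seed=11)
    return persons, meas


@pytest.fixture(scope="session")
def study(default_params):
    """Full landmark analysis at age 60 on a mid-size cohort.

    Used by the schedule-invariance, brute-force and sensitivity checks.
    """
    persons, meas = cs.simulate_cohort(default_params, 1500, seed=23)
    spec = LandmarkSpec(landmark_ages=(60.0,))
    result = cs.run_landmark_analysis(persons, meas, 60.0, spec, NbParams())
    return {"persons": persons, "measurements": meas, "spec": spec,
            "result": result}


@pytest.fixture(scope="session")
def recovery(default_params):
    """Large simulated cohort with known truth plus the fitted mixed model.

    Smoking is recorded on its latent continuous scale here: the recorded
    0/1 smoking variable identifies a linear-probability estimand rather
    than the latent-Gaussian coefficients held in TrueParams, so coefficient
    recovery is only well-posed on the latent scale.
    """
    params = default_params.replace(smoke_record="latent")
    persons, meas, ranef = cs.simulate_cohort(params, 5000, seed=5,
                                              return_truth=True)
    fit = cs.fit_lmem(meas, persons, persons["person_id"], age_center=60.0,
                      max_iter=300, tol=1e-9)
    return {"params": params, "persons": persons, "measurements": meas,
            "ranef": ranef, "fit": fit}
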