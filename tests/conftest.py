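import numpy as np
import pytest

import gsdpred as g
from gsdpred.features import cohort_functional_matrices


@pytest.fixture(scope="session")
def cv_cohort():
    """A mid-sized synthetic cohort, fully ingested and featurized.

    200 subjects, no exclusion flags, default class effects; shared by the
    cross-validation tests so the (relatively) expensive trace generation
    runs once per session.
    """
    params = g.CohortParams(
        n_subjects=200, n_equipment_error=0, n_missing_survey_heavy=0,
        n_missing_wbb=0, seed=11,
    )
    roster, traces = g.simulate_cohort(params)
    features, retained, report = g.ingest_cohort(roster, seed=1)
    ids = retained["subject_id"].tolist()
    mats = cohort_functional_matrices(traces, ids)
    y = (retained["gsd_label"] == "GSD+").to_numpy(float)
    unable = retained["flag_unable_to_complete"].to_numpy(bool)
    return {
        "roster": roster, "features": features, "retained": retained,
        "y": y, "unable": unable, "functional": mats, "report": report,
    }


@pytest.fixture()
def eight_traces():
    """One subject's 8 balance tests (4 poses x 2 trials)."""
    return {
        (pose, trial): g.simulate_cop_trace(
            "GSD-", pose, seed=100 * trial + i, trial=trial
        )
        for i, pose in enumerate(("EO_FA", "EO_FT", "EC_FA", "EC_FT"))
        for trial in (1, 2)
    }


# controlled known-truth cohorts live in the package so the analysis
# drivers and the tests share one implementation
from gsdpred.experiments import simulate_known_effect_cohort as quick_functional_cohort  # noqa: E402,F401


@pytest.fixture(scope="session")
def cv_cohort_strong():
    """A 300-subject cohort with a strong, well-identified functional effect
    (velocity ratio 3, tight per-subject effect spread) for the qualitative
    claim that balance-board information improves on the scalar model."""
    params = g.CohortParams(
        n_subjects=300, n_equipment_error=0, n_missing_survey_heavy=0,
        n_missing_wbb=0, seed=17,
    )
    sway = g.SwayParams(class_velocity_ratio=3.0, effect_sigma=0.2)
    roster, traces = g.simulate_cohort(params, sway)
    features, retained, _ = g.ingest_cohort(roster, seed=1)
    ids = retained["subject_id"].tolist()
    mats = cohort_functional_matrices(traces, ids)
    return {
        "features": features,
        "y": (retained["gsd_label"] == "GSD+").to_numpy(float),
        "unable": retained["flag_unable_to_complete"].to_numpy(bool),
        "functional": mats,
    }


@pytest.fixture(scope="session")
def recovery_cohorts():
    """Ten seeded cohorts (n=400) with a known-truth functional effect.

    Baseline sway is homogeneous (subject_scale_sigma=0) so the true
    coefficient curve is exactly null outside the [2, 6.5] s effect window;
    the per-subject effect spread 0.2 keeps the classes overlapping so the
    logistic fit stays identifiable (no separation).  The class velocity
    ratio is the generator default.
    """
    return [
        quick_functional_cohort(n=400, seed=1000 + s, ratio=2.0,
                                scale_sigma=0.0, effect_sigma=0.2)
        for s in range(10)
    ]


def make_correlated_matrix(n=200, p=8, seed=0):
    """Correlated Gaussian features for imputation benchmarks."""
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n, 1))
    return latent @ np.full((1, p), 1.0) + 0.6 * rng.standard_normal((n, p))
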