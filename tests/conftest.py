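import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tractlabel as tl

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Study-condition cohort: 7 bundles x 50 tracts, 1 mm shape noise, no
    affine jitter, 5% injected outliers; subject 0 calibrates thresholds,
    subjects 1-5 are atlases, subject 6 is the test subject."""
    spec = tl.SyntheticCohortSpec(
        n_subjects=7,
        tracts_per_bundle=50,
        shape_noise_sd=1.0,
        subject_affine_jitter=tl.AffineJitter(0.0, 0.0, 0.0),
        outlier_fraction=0.05,
        seed=0,
    )
    return tl.build_synthetic_cohort(spec)


@pytest.fixture(scope="session")
def recovery_atlases(recovery_cohort):
    atlases = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(1, 6):
            subj = recovery_cohort[s]
            labels = {
                i: ("unlabeled" if l == tl.OUTLIER_TRUE else str(l))
                for i, l in enumerate(subj.labels)
            }
            grouping = tl.group_subject(subj.tract_set)
            atlases.append(
                tl.build_atlas(
                    subj.tract_set, labels, grouping, subject_id=f"s{s}",
                    affine=subj.affine_to_reference,
                )
            )
    return atlases


@pytest.fixture(scope="session")
def calibrated_taus(recovery_cohort, recovery_atlases):
    calib = recovery_cohort[0]
    return tl.calibrate_thresholds(recovery_atlases, calib.tract_set, calib.labels)
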