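"""Shared fixtures.

The expensive multi-seed cohort experiment used by the acceptance-level
tests is computed once per session and shared; everything else builds its
own small inputs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import fusionhar as fh


@pytest.fixture(scope="session")
def small_record():
    """One simulated subject: 30 s of each activity (fast, deterministic)."""
    params = fh.SubjectParams(subject_id="S01")
    return fh.simulate_subject(params, fh.default_protocol(30.0), seed=42)


@pytest.fixture(scope="session")
def small_cohort_features():
    """Feature matrix for a 4-subject, 60 s/activity cohort."""
    recs = fh.simulate_cohort(4, protocol=fh.default_protocol(60.0), seed=7)
    return fh.cohort_feature_matrix(recs)


@pytest.fixture(scope="session")
def cohort_experiment():
    """The 5-seed, 10-subject study-condition experiment.

    For each master seed: LOSO over scenarios 1-4 and subject-specific over
    scenarios 1-3 on a cohort of 10 subjects with 120 s per activity.
    Returns {seed: {"loso": {scenario: (results, mean)},
                    "subject": {scenario: (results, mean)}}}.
    """
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(1, 6):
            recs = fh.simulate_cohort(10, seed=seed)
            feats = fh.cohort_feature_matrix(recs)
            spec = fh.ModelSpec(seed=seed)
            loso = {sc: fh.loso_eval(feats, sc, spec, seed=seed) for sc in (1, 2, 3, 4)}
            # cv_folds=0 skips the per-fold CV diagnostics; the hold-out
            # scores (all that these tests compare) are unchanged by it
            subj = {
                sc: fh.subject_specific_cohort(feats, sc, spec, seed=seed, cv_folds=0)
                for sc in (1, 2, 3)
            }
            out[seed] = {"loso": loso, "subject": subj}
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
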