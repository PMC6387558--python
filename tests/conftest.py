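"""Shared fixtures: a default atlas and a small preprocessed cohort.

Session-scoped so the phantom generation and smoothing cost is paid once
across the unit-test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from dlbpet.phantom import CohortSpec, make_atlas, make_cohort
from dlbpet.preprocess import preprocess_cohort
from dlbpet.tmap import extract_clusters, fit_subject_tmap, fwe_threshold


@pytest.fixture(scope="session")
def atlas():
    return make_atlas()


@pytest.fixture(scope="session")
def small_cohort(atlas):
    """20 controls plus one patient per pattern, preprocessed."""
    spec = CohortSpec(n_controls=20,
                      n_patients={"DLB": 1, "ADD": 1, "PCA": 1, "PD": 1},
                      seed=11)
    controls, patients, meta = make_cohort(spec, atlas)
    sc, sp, mask = preprocess_cohort(controls, patients)
    return {"controls": sc, "patients": sp, "mask": mask, "meta": meta,
            "spec": spec}


@pytest.fixture(scope="session")
def patient_analyses(atlas, small_cohort):
    """t-map, FWE threshold and clusters for each patient of the small
    cohort, keyed by generating pattern."""
    out = {}
    for scan in small_cohort["patients"]:
        tm = fit_subject_tmap(scan, small_cohort["controls"],
                              small_cohort["mask"])
        thr = fwe_threshold(tm, 0.05)
        clusters = extract_clusters(tm, thr)
        out[scan.pattern] = {"scan": scan, "tmap": tm, "threshold": thr,
                             "clusters": clusters}
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
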