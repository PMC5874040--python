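"""Shared fixtures: a seeded synthetic cohort aligned once per session.

The cohort reflects the study conditions of the simulation experiments:
five test embryos with temporal offsets up to +/-20 min, size jitter up to
5% (length) / 4% (width), total rotations drawn from N(34.8, 47.5) deg and
per-step magnitudes from N(1.7, 1.4) deg, generated noise-free so that
alignment error is attributable to the pipeline itself.
"""

from __future__ import annotations

import numpy as np
import pytest

from embryoalign.mapping import PipelineConfig, align_cohort, overlap_by_stage
from embryoalign.synthetic import make_cohort

COHORT_SEED = 11
N_TEST = 5


@pytest.fixture(scope="session")
def cohort():
    ref, ref_truth, tests, truths = make_cohort(
        n_test=N_TEST, seed=COHORT_SEED, noise_free=True
    )
    return {"ref": ref, "ref_truth": ref_truth, "tests": tests, "truths": truths}


@pytest.fixture(scope="session")
def cohort_alignments(cohort):
    cfg = PipelineConfig(seed=3)
    results = align_cohort(cohort["ref"], cohort["tests"], cfg)
    return {"config": cfg, "results": results}


@pytest.fixture(scope="session")
def cohort_overlaps(cohort, cohort_alignments):
    tables = []
    for test, res in zip(cohort["tests"], cohort_alignments["results"]):
        tables.append(overlap_by_stage(test, cohort["ref"], res))
    return tables


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
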