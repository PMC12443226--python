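"""Shared fixtures: the synthetic cohort and one full two-stage tiny run.

The two-stage run is session-scoped because it is the expensive part of the
suite (a couple of minutes on one CPU); several tests inspect different
aspects of the same run (learnability, risk recovery, freeze contract).
"""

import numpy as np
import pytest

from amdmamba.backbone import build_backbone
from amdmamba.config import tiny_config
from amdmamba.synthetic import GeneratorConfig, generate_cohort
from amdmamba.training import make_folds, train_stage1, train_stage2

SEED = 0


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(GeneratorConfig(seed=SEED))


@pytest.fixture(scope="session")
def fold0(tiny_cohort):
    folds = make_folds(tiny_cohort.covariates["subject_id"], 5, seed=SEED)
    return folds[0]


@pytest.fixture(scope="session")
def stage1_run(tiny_cohort, fold0):
    _, val_subjects = fold0
    cfg = tiny_config()
    res = train_stage1(
        tiny_cohort.images,
        tiny_cohort.covariates["severity_score"].to_numpy(),
        tiny_cohort.covariates["subject_id"].to_numpy(),
        cfg,
        seed=SEED,
        val_subjects=val_subjects,
    )
    return cfg, res


@pytest.fixture(scope="session")
def stage2_run(tiny_cohort, fold0, stage1_run):
    cfg, s1 = stage1_run
    _, val_subjects = fold0
    hashes_before = (s1.backbone.state_hash(), s1.classifier.state_hash())
    res = train_stage2(
        tiny_cohort.images,
        tiny_cohort.covariates,
        tiny_cohort.survival,
        s1,
        cfg,
        seed=SEED,
        val_subjects=val_subjects,
    )
    hashes_after = (s1.backbone.state_hash(), s1.classifier.state_hash())
    return {"result": res, "hashes_before": hashes_before, "hashes_after": hashes_after}


@pytest.fixture
def tiny_backbone():
    return build_backbone(tiny_config().backbone, seed=3)
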