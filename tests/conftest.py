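"""Shared fixtures: phantom cohorts and a trained breast segmenter.

The segmenter is trained once per session on 40 phantom MIPs and reused by
every test that needs learned breast masks.
"""

from __future__ import annotations

import numpy as np
import pytest

from bpequant.breast_seg import train_segmenter
from bpequant.phantom import PhantomSpec, generate_cohort, generate_study
from bpequant.projection import project
from bpequant.volumes import subtract


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


def mip_mask_pairs(cohort):
    return [
        (project(subtract(study, 2), "MIP").data, truth.breast_projection_mask())
        for study, truth in cohort
    ]


@pytest.fixture(scope="session")
def training_cohort():
    cohort, _ = generate_cohort(n=40, seed=101)
    return cohort


@pytest.fixture(scope="session")
def holdout_cohort():
    cohort, _ = generate_cohort(n=10, seed=202)
    return cohort


@pytest.fixture(scope="session")
def segmenter(training_cohort):
    return train_segmenter(mip_mask_pairs(training_cohort), epochs_max=15, seed=0)


@pytest.fixture(scope="session")
def lesion_phantom():
    """Moderate-BPE phantom with a 15 mm lesion in the left breast."""
    spec = PhantomSpec(bpe_level="moderate", lesion_diameter_mm=15.0,
                       lesion_side="left", seed=7)
    study, truth = generate_study(spec)
    return spec, study, truth
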