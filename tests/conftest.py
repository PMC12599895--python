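"""Shared fixtures: phantom patients, a fully processed screening pair,
and synthetic feature matrices with planted signal."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from subtracad import phantom, preprocess, register, subtract, detect

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_config() -> phantom.CohortConfig:
    return phantom.CohortConfig()


@pytest.fixture(scope="session")
def malignant_patient(default_config):
    """One malignant patient (all views/rounds) with ground truth."""
    return phantom.generate_patient(
        default_config, "P0", 7, patient_label="malignant", density="c"
    )


@pytest.fixture(scope="session")
def processed_pair(default_config, malignant_patient):
    """The CC pair of the malignant patient taken through preprocessing,
    Demons registration and temporal subtraction."""
    imgs, gt = malignant_patient
    prior, recent = imgs[0], imgs[1]
    recent_pp, recent_mask = preprocess.preprocess_pipeline(recent)
    prior_pp, prior_mask = preprocess.preprocess_pipeline(prior)
    warped, field = register.demons_register(recent_pp.pixels, prior_pp.pixels)
    residual = subtract.temporal_subtract(recent_pp, warped, recent_mask)
    residual.pixels[warped <= 0] = 0.0
    return {
        "gt": gt,
        "prior": prior,
        "recent": recent,
        "recent_pp": recent_pp,
        "prior_pp": prior_pp,
        "recent_mask": recent_mask,
        "prior_mask": prior_mask,
        "warped": warped,
        "field": field,
        "residual": residual,
    }


@pytest.fixture(scope="session")
def detected_rois(processed_pair):
    res = processed_pair["residual"]
    rois = detect.segment_candidates(res)
    gt = processed_pair["gt"]
    detect.match_to_truth(rois, gt.mass_masks["CC"], ["malignant"] * len(gt.mass_masks["CC"]))
    return rois


def make_planted_features(
    n: int = 200,
    n_features: int = 98,
    n_informative: int = 5,
    effect: float = 1.5,
    seed: int = 0,
    n_patients: int = 50,
):
    """Feature matrix with `n_informative` class-shifted columns among
    pure-noise ones, plus patient grouping.

    Returns (X, y, groups, informative_indices).
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, n_features))
    informative = rng.choice(n_features, size=n_informative, replace=False)
    for f in informative:
        X[:, f] += effect * y
    groups = rng.integers(0, n_patients, n)
    return X, y, groups, np.sort(informative)
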