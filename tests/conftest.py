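"""Shared fixtures: small synthetic cohorts reused across the suite.

Most tests run on reduced cohorts synthesized natively at 250 Hz (the
analysis rate) to keep the suite fast; the acquisition-rate path
(1000 Hz + downsampling) is exercised explicitly where it matters.
"""
from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from drivewave.biomarkers import build_feature_table
from drivewave.preprocess import PreprocessConfig, preprocess, segment_epochs
from drivewave.spectra import extract_features
from drivewave.synth import StateSpec, default_state_specs, synthesize_cohort


@pytest.fixture(scope="session")
def small_specs() -> dict[str, StateSpec]:
    """4 subjects, (3, 6, 6) feature epochs per state."""
    eps = {"resting": 3, "city_roadway": 6, "expressway": 6}
    return {
        s: replace(sp, n_subjects=4, epochs_per_subject=eps[s])
        for s, sp in default_state_specs().items()
    }


@pytest.fixture(scope="session")
def small_cohort(small_specs):
    """Clean 4-subject cohort recording, 250 Hz native."""
    return synthesize_cohort(small_specs, seed=11, fs=250.0)


@pytest.fixture(scope="session")
def small_epochs(small_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = preprocess(small_cohort)
        return segment_epochs(rec)


@pytest.fixture(scope="session")
def small_tidy(small_epochs) -> pd.DataFrame:
    return extract_features(small_epochs)


@pytest.fixture(scope="session")
def small_table(small_tidy) -> pd.DataFrame:
    return build_feature_table(small_tidy)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def tone_epoch(freq_hz: float, fs: float, dur_s: float = 10.0, amp: float = 1.0):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t)


@pytest.fixture()
def alpha_only_spec() -> StateSpec:
    """Degenerate single-band spec: all power in alpha, zero spread."""
    eps = 1e-9
    return StateSpec(
        state="alpha_only",
        band_relpower_mean={
            "delta": eps, "theta": eps, "alpha": 1.0, "beta": eps, "gamma": eps,
        },
        band_relpower_sd={b: 0.0 for b in
                          ("delta", "theta", "alpha", "beta", "gamma")},
        n_subjects=1,
        epochs_per_subject=1,
    )
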