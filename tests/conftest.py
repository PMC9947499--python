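"""Shared fixtures.

The expensive fixtures (a full critical-dynamics recording pushed through
the classification chain, and two cohort-level feature tables) are session
scoped so the unit, property and acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from brainfog_eeg import avalanche, preprocess, synth

# fixed study-condition seeds for the shipped fixtures
CRITICAL_SEED = 11
COHORT_EFFECT_SEED = 2026
COHORT_NULL_SEED = 515


@pytest.fixture(scope="session")
def critical_fixture():
    """Critical cascades (sigma_true = 1) rendered into a 137-channel,
    5-minute recording and preprocessed with the classification chain.

    Returns (clean_recording, truth_table, cascades, sigma_true).
    """
    sigma_true = 1.0
    cascades = synth.simulate_branching_cascades(
        n_channels=137, sigma=sigma_true, n_avalanches=900,
        seed=CRITICAL_SEED, max_duration=25,
    )
    rec, truth = synth.render_resting_recording(
        cascades, fs=250.0, duration_s=300.0, seed=CRITICAL_SEED + 1,
    )
    clean = preprocess.run_classification_pipeline(rec)
    return clean, truth, cascades, sigma_true


def _features(specs, seed, duration_s):
    subjects = synth.build_cohort_dataset(
        specs, seed=seed, duration_s=duration_s, fs=250.0,
        include_resting=True, paradigms=(),
    )
    cleaned = [
        preprocess.run_classification_pipeline(s.resting) for s in subjects
    ]
    return avalanche.features_table(cleaned)


@pytest.fixture(scope="session")
def cohort_features_effect():
    """Feature table for 20/20/20 subjects with the default branching-
    parameter shift of 0.15 between the COVID cohorts (A, B) and controls."""
    specs = synth.default_cohort_specs(delta_sigma=0.15, n_subjects=20)
    return _features(specs, COHORT_EFFECT_SEED, duration_s=120.0)


@pytest.fixture(scope="session")
def cohort_features_null():
    """Feature table for 27/27/27 subjects with no injected effect."""
    specs = synth.default_cohort_specs(delta_sigma=0.0, n_subjects=27)
    return _features(specs, COHORT_NULL_SEED, duration_s=60.0)


def detected_event_sets(clean, threshold_sd: float = 2.7):
    """Per-channel sets of detected event samples for recovery matching."""
    z = avalanche.zscore_channels(clean)
    events = avalanche.extract_events(z, threshold_sd)
    return [set(idx.tolist()) for idx in events]


def event_recovery_fraction(clean, truth, source_fs: float = 250.0,
                            tol_samples: int = 3) -> float:
    """Fraction of injected events matched by a detection on the same
    channel within ``tol_samples`` of the downsampled injection sample."""
    det = detected_event_sets(clean)
    decim = int(round(source_fs / clean.fs))
    hits = 0
    for ch, s in zip(truth["channel"], truth["sample"]):
        target = s // decim
        if any((target + d) in det[ch] for d in range(-tol_samples, tol_samples + 1)):
            hits += 1
    return hits / len(truth)
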