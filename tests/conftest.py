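"""Shared fixtures: one synthetic cohort and one trained bundle per session."""

import numpy as np
import pytest

import wearact as wa

COHORT_SEED = 7


@pytest.fixture(scope="session")
def cohort():
    """8 training subjects; 20 test subjects, 10 rotated, 2 WWS-biased."""
    return wa.make_cohort(
        n_train=8, n_test=20, fraction_rotated=0.5, fraction_wws=0.1,
        master_seed=COHORT_SEED,
    )


@pytest.fixture(scope="session")
def bundle(cohort):
    return wa.train_bundle(
        [s.recording for s in cohort.train],
        [s.track for s in cohort.train],
    )


@pytest.fixture(scope="session")
def upright_subjects(cohort):
    return [s for s in cohort.test if not s.rotated and not s.biased]


@pytest.fixture(scope="session")
def rotated_subjects(cohort):
    return [s for s in cohort.test if s.rotated]


@pytest.fixture(scope="session")
def single_recording():
    params = wa.SynthSubjectParams(seed=3)
    return wa.simulate_recording(params, subject_id="solo")


def cohort_windows(subjects):
    """Stack labelled 9-channel windows of cohort subjects."""
    mats, labels = [], []
    for s in subjects:
        ws = wa.segment_windows(s.recording, wa.build_labels(s.track))
        keep = [i for i, l in enumerate(ws.labels) if l is not None]
        mats.append(ws.data[keep])
        labels += [ws.labels[i] for i in keep]
    return np.vstack(mats), labels
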