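import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from neckppg import SynthConfig, normalize_recording, synth_cohort
from neckppg.windowing import extract_cohort_features


@pytest.fixture(scope="session")
def small_cohort():
    """Three-subject cohort for unit-level checks (fast to generate)."""
    return synth_cohort(SynthConfig(n_subjects=3, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 12 subjects, 13 recordings each."""
    return synth_cohort(SynthConfig(seed=5))


@pytest.fixture(scope="session")
def default_features_w6(default_cohort):
    """Label-free window features at W=6 s for the default cohort.

    Shared across end-to-end tests; feature extraction does not depend on
    task, threshold or repetition.
    """
    return extract_cohort_features(default_cohort, 6.0)


@pytest.fixture(scope="session")
def small_features_w6(small_cohort):
    return extract_cohort_features(small_cohort, 6.0)


@pytest.fixture()
def sinusoid_recording():
    """A pure 1.2 Hz sinusoid packaged as a normalized recording."""
    from neckppg import Recording

    fs = 75.0
    t = np.arange(int(30 * fs)) / fs
    x = np.sin(2 * np.pi * 1.2 * t)
    rec = Recording("Ssin", "sin12", "control", fs, x)
    return normalize_recording(rec)
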