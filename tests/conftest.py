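import numpy as np
import pytest

import qeegkit as qk
from qeegkit.simulate import default_profile


@pytest.fixture(scope="session")
def control_recording():
    """One 120-s control-profile subject (dominant 10.5-Hz posterior alpha)."""
    return qk.generate_subject(default_profile("control"), duration_s=120.0,
                               fs=512.0, seed=11, subject_id="ctl011")


@pytest.fixture(scope="session")
def control_result(control_recording):
    return qk.analyze_subject(control_recording)


@pytest.fixture(scope="session")
def small_ds_results():
    """Five analyzed DS-profile subjects (2 asynchronous)."""
    cohort = qk.generate_cohort(qk.CohortSpec(
        n_subjects=5, group="ds", asynchrony_fraction=2 / 5, seed=21))
    return [qk.analyze_subject(rec) for rec, _ in cohort]


def flat_spectrum(value: float = 1.0, fmax: float = 256.0,
                  labels=("x",)):
    """SpectrumSet with constant density on the standard 0.5-Hz grid."""
    freqs = np.arange(0.0, fmax + 0.25, 0.5)
    S = np.full((1, len(labels), len(freqs)), float(value))
    return qk.SpectrumSet(freqs=freqs, S=S, labels=list(labels))
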