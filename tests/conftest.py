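import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

RATE = 44100


@pytest.fixture(scope="session")
def tone_waveform():
    """One second of a clean 220 Hz sine at the reference rate."""
    from pdnet.speech import Waveform

    t = np.arange(RATE) / RATE
    return Waveform(np.sin(2 * np.pi * 220 * t), RATE)


@pytest.fixture(scope="session")
def tone_gap_tone():
    """0.5 s tone, 0.4 s silence, 0.5 s tone: two internal transitions."""
    from pdnet.speech import Waveform

    t = np.arange(int(0.5 * RATE)) / RATE
    tone = np.sin(2 * np.pi * 180 * t)
    x = np.concatenate([tone, np.zeros(int(0.4 * RATE)), tone])
    return Waveform(x, RATE)


@pytest.fixture(scope="session")
def healthy_page():
    """Rendered healthy-writing page at 300 dpi with its ground truth."""
    from pdnet.synth import PageProfile, synth_page

    return synth_page(PageProfile(seed=11), n_lines=8, strokes_per_line=20, dpi=300.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared by synthesis/pipeline tests."""
    from pdnet.synth import CohortSpec, generate_cohort_images

    spec = CohortSpec(n_cases=3, n_controls=2, speech_duration_s=12.0,
                      n_lines=8, strokes_per_line=22, seed=7)
    return spec, generate_cohort_images(spec)
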