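"""Shared fixtures: designed tracts, converged focused state, synthetic clips.

The expensive pipeline stages (formant merging, synthesis) are computed once
per session and reused across test modules.
"""

import numpy as np
import pytest

from khoomei.acoustics import (
    AcousticConstants,
    compute_frequency_response,
    perturb_to_focus,
)
from khoomei.analysis import StftParams, compute_spectrogram
from khoomei.geometry import AreaFunction
from khoomei.simulate import make_designed_area_function
from khoomei.synthesis import GlottalSourceSpec, synthesize_static


@pytest.fixture(scope="session")
def constants():
    return AcousticConstants()


@pytest.fixture(scope="session")
def lossless():
    return AcousticConstants.lossless()


@pytest.fixture(scope="session")
def uniform_tube():
    """17.5 cm closed-open tube of 3 cm^2 (quarter-wave oracle geometry)."""
    return AreaFunction(np.linspace(0.0, 17.5, 45), np.full(45, 3.0))


@pytest.fixture(scope="session")
def neutral_tract():
    return make_designed_area_function()


@pytest.fixture(scope="session")
def focus_result(neutral_tract, constants):
    """F2/F3 merged onto 1800 Hz from the designed neutral tract."""
    res = perturb_to_focus(neutral_tract, constants, 1800.0, (2, 3))
    assert res.converged
    return res


@pytest.fixture(scope="session")
def focused_response(focus_result, constants):
    return compute_frequency_response(
        focus_result.af, constants, kind="radiated_pressure"
    )


@pytest.fixture(scope="session")
def neutral_response(neutral_tract, constants):
    return compute_frequency_response(
        neutral_tract, constants, kind="radiated_pressure"
    )


@pytest.fixture(scope="session")
def source_150():
    return GlottalSourceSpec(f0=150.0)


@pytest.fixture(scope="session")
def focused_clip(source_150, focused_response):
    return synthesize_static(source_150, focused_response, duration=2.0)


@pytest.fixture(scope="session")
def normal_clip(source_150, neutral_response):
    return synthesize_static(source_150, neutral_response, duration=2.0)


@pytest.fixture(scope="session")
def stft_2048():
    return StftParams(window_samples=2048, overlap=0.95)


@pytest.fixture(scope="session")
def focused_spec(focused_clip, stft_2048):
    return compute_spectrogram(focused_clip, stft_2048)


@pytest.fixture(scope="session")
def normal_spec(normal_clip, stft_2048):
    return compute_spectrogram(normal_clip, stft_2048)
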