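import numpy as np
import pytest

from cyclogait import StudySpec, diabetic_template, generate_recording, healthy_template


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=["healthy", "diabetic"])
def template(request):
    return healthy_template() if request.param == "healthy" else diabetic_template()


@pytest.fixture
def noiseless_recording():
    """Deterministic 6-stride recording with zero marker scatter."""
    tpl = healthy_template()
    rec, truth = generate_recording(tpl, StudySpec(), seed=0, sigma_factor=0.0)
    return tpl, rec, truth


@pytest.fixture
def noisy_recording():
    """6-stride recording with the template's full per-cluster scatter."""
    tpl = diabetic_template()
    rec, truth = generate_recording(tpl, StudySpec(), seed=42, sigma_factor=1.0)
    return tpl, rec, truth
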