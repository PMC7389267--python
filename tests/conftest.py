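import numpy as np
import pytest

from dfskit import CurveMetadata, ForceCurve, REFERENCE_LANDSCAPES


@pytest.fixture
def metadata():
    return CurveMetadata(curve_id="c001", spring_constant=10.0, retract_speed=1.0)


@pytest.fixture
def flat_curve(metadata):
    """Noise-free flat curve: 512 approach + 512 retract samples."""
    n = 512
    t = np.arange(2 * n) / 2000.0
    h = np.concatenate([np.linspace(600.0, -50.0, n), np.linspace(-50.0, 600.0, n)])
    f = np.zeros(2 * n)
    seg = np.array(["approach"] * n + ["retract"] * n)
    return ForceCurve(metadata=metadata, time=t, height=h, force=f, segment=seg)


@pytest.fixture(params=range(len(REFERENCE_LANDSCAPES)),
                ids=[ref.substrate for ref in REFERENCE_LANDSCAPES])
def reference_landscape(request):
    """One of the four published probe/substrate parameter sets."""
    return REFERENCE_LANDSCAPES[request.param]
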