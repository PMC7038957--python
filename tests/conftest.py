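import numpy as np
import pytest

from afscreen import synthetic as syn
from afscreen.core import ChartRenderConfig

#: the six-interval RR series used throughout the symbolization examples
EXAMPLE_RR = (0.55, 0.65, 0.60, 0.70, 0.65, 0.50)


@pytest.fixture(scope="session")
def example_rr():
    return np.asarray(EXAMPLE_RR)


@pytest.fixture(scope="session")
def rendered_chart():
    """A noiseless synthetic NS strip rendered at default 600 dpi geometry.

    Returns (image, cfg, source_signal, true_peak_indices, rr_series).
    """
    rr = syn.generate_rr_ns(10, seed=7)
    signal, peaks = syn.synthesize_ecg(rr)
    cfg = ChartRenderConfig()
    img = syn.render_chart(signal, cfg)
    return img, cfg, signal, peaks, rr
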