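import numpy as np
import pandas as pd
import pytest

from stereotrack.amplitude import AmplitudeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_series():
    """Factory wrapping raw values into an AmplitudeSeries on a 25 fps grid."""

    def factory(values, fps=25.0, track_id=1):
        values = np.asarray(values, dtype=float)
        return AmplitudeSeries(
            track_id=track_id, fps=fps, t=np.arange(len(values)) / fps, r=values
        )

    return factory


@pytest.fixture
def static_tracks():
    """Factory for frame-indexed track tables of static boxes.

    spec: {track_id: (frames, x_offset)} -> tidy DataFrame; every box is
    40x80 px at the given horizontal offset.
    """

    def factory(spec):
        rows = []
        for tid, (frames, x0) in spec.items():
            for f in frames:
                rows.append((f, tid, x0, 0.0, x0 + 40.0, 80.0, 1.0))
        return pd.DataFrame(
            rows, columns=["frame", "id", "x1", "y1", "x2", "y2", "conf"]
        )

    return factory
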