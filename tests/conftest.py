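import numpy as np
import pytest

from rheo.tracks import FlowFrame, Track


@pytest.fixture
def frame() -> FlowFrame:
    """Flow toward −x, so upstream is +x."""
    return FlowFrame((-1.0, 0.0))


def straight_track(rate_um_min: float, direction=(1.0, 0.0),
                   duration_s: float = 60.0, dt_s: float = 1.0,
                   cell_id: str = "cell", orientation: str = "unknown") -> Track:
    """Constant-velocity track at the given net rate along ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.hypot(*d)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    xy = np.outer(t, d) * (rate_um_min / 60.0)
    return Track(cell_id=cell_id, t_s=t, x_um=xy[:, 0], y_um=xy[:, 1],
                 orientation=orientation)
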