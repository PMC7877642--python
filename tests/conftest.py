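import numpy as np
import pytest

from gutmotion import DiameterMatrix, default_params


@pytest.fixture(scope="session")
def cellulose_params():
    """Calibrated defaults; session-scoped because calibration costs ~30 s."""
    return default_params("cellulose")


@pytest.fixture
def small_dm():
    """3 positions x 3 frames of 5.0 mm, 1 mm spacing, 1 s frames."""
    return DiameterMatrix(
        values=np.full((3, 3), 5.0),
        position_spacing_mm=1.0,
        frame_interval_s=1.0,
        preparation_id="tiny",
        treatment="empty",
    )


def make_dm(values, spacing=0.25, interval=1.0, **kw):
    return DiameterMatrix(values=np.asarray(values, dtype=float),
                          position_spacing_mm=spacing,
                          frame_interval_s=interval, **kw)
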