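import numpy as np
import pandas as pd
import pytest

from rootmitosis import EventTable


@pytest.fixture
def tiny_table() -> EventTable:
    """Hand-built two-condition table: 6 events, 4 frames, Δt = 0.25 h."""
    df = pd.DataFrame(
        {
            "event_id": [f"e{i}" for i in range(6)],
            "root_id": ["intact_1", "intact_1", "intact_1", "regen_1", "regen_1", "regen_1"],
            "condition": ["intact"] * 3 + ["regenerating"] * 3,
            "frame_index": [0, 0, 2, 1, 2, 3],
            "x_um": [0.0, 10.0, 50.0, 5.0, 60.0, 30.0],
            "y_um": [0.0, 0.0, 50.0, 5.0, 60.0, 30.0],
            "z_um": [0.0, 0.0, 50.0, 5.0, 60.0, 30.0],
        }
    )
    return EventTable(df, delta_t_h=0.25, n_frames=4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
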