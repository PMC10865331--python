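import numpy as np
import pandas as pd
import pytest

from feedkit import (
    SessionDesign,
    SynthSpec,
    ZoneConfig,
    default_zone,
    random_session_spec,
)
from feedkit.pose_io import COORDS, PoseTrack


def make_track(arrays: dict, fps: float = 30.0) -> PoseTrack:
    """Build a PoseTrack from {part: (x, y, likelihood) arrays}."""
    parts = list(arrays)
    n = len(arrays[parts[0]][0])
    cols = pd.MultiIndex.from_product([parts, COORDS])
    data = np.column_stack(
        [np.asarray(arr, float) for part in parts for arr in arrays[part]]
    )
    return PoseTrack(data=pd.DataFrame(data, columns=cols), fps=fps)


@pytest.fixture
def zone() -> ZoneConfig:
    return default_zone()


@pytest.fixture
def one_food_design() -> SessionDesign:
    return SessionDesign(
        subject_id="A",
        internal_state="hunger",
        food="palatable",
        condition="artificial-1",
        test_type="one-food",
    )


@pytest.fixture
def pairwise_design() -> SessionDesign:
    return SessionDesign(
        subject_id="A",
        internal_state="neutral",
        food="pairwise",
        condition="natural",
        test_type="pairwise",
    )


@pytest.fixture
def planted_spec() -> SynthSpec:
    """Hand-written schedule: 5 tray entries, 3 valid bouts, 100 s occupancy."""
    return SynthSpec(
        duration=120.0,
        tray_entry_times={"left": [10.0, 30.0], "right": [20.0, 50.0, 70.0]},
        bout_lags=[
            ("left", 10.0, 2.0),
            ("right", 20.0, 1.5),
            ("right", 50.0, 2.5),
        ],
        occupancy_segments=[(5.0, 55.0), (60.0, 110.0)],
    )


@pytest.fixture
def random_spec() -> SynthSpec:
    return random_session_spec(seed=11)
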