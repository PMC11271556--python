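import numpy as np
import pytest

from mfrkit.study import (
    SEGMENT_IDS,
    DynamicStudy,
    RegionTAC,
    default_frame_schedule,
)
from mfrkit.synth import gamma_variate_aif, simulate_true_tac


@pytest.fixture(scope="session")
def schedule():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def aif(schedule):
    """Default noiseless bolus: frame TAC plus the fine-grid curve."""
    tac, t, fine = gamma_variate_aif(schedule)
    return tac, t, fine


def make_study(schedule, blood_values, segment_matrix, condition="rest",
               extracardiac=None):
    segs = {
        s: RegionTAC(s, np.asarray(segment_matrix[i], dtype=float))
        for i, s in enumerate(SEGMENT_IDS)
    }
    return DynamicStudy(
        condition=condition,
        schedule=schedule,
        blood=RegionTAC("blood", np.asarray(blood_values, dtype=float)),
        segments=segs,
        extracardiac=(
            None if extracardiac is None else RegionTAC("extracardiac", extracardiac)
        ),
    )


@pytest.fixture(scope="session")
def uniform_study(schedule, aif):
    """All 17 segments share one noiseless one-compartment TAC."""
    tac, t, fine = aif
    seg = simulate_true_tac(0.8, 0.15, 0.3, t, fine, schedule)
    return make_study(schedule, tac.values, np.tile(seg, (17, 1)))
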