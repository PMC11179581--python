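import numpy as np
import pandas as pd
import pytest

from dopaq import PopulationParams, simulate_copas_population
from dopaq.flow import Condition, GatedCondition
from dopaq.tfscreen import read_jaspar

JASPAR_TEXT = """\
>SYN0001 synTF1
A  [  2   2  24   2   2   2  24   2 ]
C  [  2   2   2  24   2  24   2   2 ]
G  [  2  24   2   2   2   2   2   2 ]
T  [ 24   2   2   2  24   2   2  24 ]
"""


@pytest.fixture(scope="session")
def pwm():
    return read_jaspar(JASPAR_TEXT)[0]


@pytest.fixture(scope="session")
def small_population():
    return simulate_copas_population(
        PopulationParams(n_worms=100, seed=42), Condition(treatment="uninjured")
    )


def make_gated(pos_405, pos_488, neg_405, neg_488, timepoint_h=0.0, treatment="uninjured"):
    """Hand-built GatedCondition from explicit channel values."""

    def frame(v405, v488):
        n = len(v405)
        return pd.DataFrame(
            {
                "worm_id": [f"w{i}" for i in range(n)],
                "condition": "x",
                "treatment": treatment,
                "timepoint_h": timepoint_h,
                "replicate": 1,
                "extinction_peak": 1.0,
                "tof": 1.0,
                "gfp488_peak": np.asarray(v488, dtype=float),
                "gfp405_peak": np.asarray(v405, dtype=float),
                "mcherry_peak": 0.0,
            }
        )

    return GatedCondition(
        mch_pos=frame(pos_405, pos_488),
        mch_neg=frame(neg_405, neg_488),
        threshold=1.0,
        condition=Condition(treatment=treatment, timepoint_h=timepoint_h),
    )
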