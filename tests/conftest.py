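import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ephyskit import synth

settings.register_profile("det", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def protocol():
    return synth.StimProtocol()


@pytest.fixture(scope="session")
def if_session():
    """Noiseless adaptive integrate-and-fire session (default step ladder)."""
    return synth.gen_current_step_session(seed=11)


def make_unit_trials(counts, blank_counts, protocol, unit_id="u0",
                     mouse_id="m0"):
    """Assemble a tidy trial table for one unit from a (2, K, R) count
    array and a blank-count vector."""
    ori = protocol.orientations_deg
    rows = []
    for ei, eye in enumerate(("contra", "ipsi")):
        for ki, o in enumerate(ori):
            for r in range(protocol.repeats_per_condition):
                rows.append((mouse_id, unit_id, eye, o, r + 1,
                             counts[ei, ki, r]))
    for r, c in enumerate(blank_counts):
        rows.append((mouse_id, unit_id, "blank", np.nan, r + 1, c))
    df = pd.DataFrame(rows, columns=["mouse_id", "unit_id", "eye",
                                     "orientation_deg", "repeat",
                                     "spike_count"])
    df["stim_s"] = protocol.stim_duration
    df["trial_s"] = protocol.trial_duration
    return df
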