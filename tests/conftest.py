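import numpy as np
import pandas as pd
import pytest

from piece import ProtocolConfig, build_protocol, simulate_participant
from piece.params import PieceParams


@pytest.fixture(scope="session")
def default_params():
    return PieceParams()


@pytest.fixture(scope="session")
def protocol():
    """One full-size randomized schedule, shared across tests."""
    return build_protocol(ProtocolConfig(), seed=11)


@pytest.fixture(scope="session")
def piece_trials(protocol, default_params):
    """One PIECE participant simulated over the full schedule."""
    return simulate_participant("PIECE", default_params, protocol, seed=21)


def make_trials(rot, hand, participant_id="T01", ttype=None):
    """Hand-crafted trial table from explicit per-trial arrays.

    ``rot``/``hand`` give per-trial rotation and reach angle.  By default
    every interior odd position is a measured trial and the rest are
    nulls (strict alternation); pass ``ttype`` for other schedules.  Used
    to build exact, noiseless fixtures for regression and likelihood
    oracles.
    """
    n = len(hand)
    if ttype is None:
        ttype = ["measured" if (i % 2 == 1 and i < n - 1) else "null" for i in range(n)]
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_index": np.arange(n),
            "block": 0,
            "phase": "main",
            "trial_type": ttype,
            "rotation_deg": [r if t == "measured" else 0.0 for r, t in zip(rot, ttype)],
            "feedback": "full",
            "hand_angle_deg": np.asarray(hand, dtype=float),
            "excluded": False,
        }
    )
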