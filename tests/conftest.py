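import numpy as np
import pytest

from dimerlens.msm import MSMEstimate
from dimerlens.synthetic import build_toy_dimer


METASTABLE_4STATE = np.array([
    [0.88, 0.10, 0.01, 0.01],
    [0.10, 0.88, 0.01, 0.01],
    [0.01, 0.01, 0.88, 0.10],
    [0.01, 0.01, 0.10, 0.88],
])


@pytest.fixture(scope="session")
def toy_dimer():
    """Scripted geometric trajectory: TM4|TM4, monomer, TM6|TM6 segments."""
    schedule = [("TM4|TM4", 60), ("monomer", 25), ("TM6|TM6", 15)]
    pair, traj, truth = build_toy_dimer(schedule, seed=11)
    return pair, traj, truth


def birth_death_msm() -> MSMEstimate:
    """Hand-solvable 3-state birth-death chain (pi by detailed balance)."""
    P = np.array([[0.5, 0.5, 0.0], [0.25, 0.5, 0.25], [0.0, 0.5, 0.5]])
    pi = np.array([0.25, 0.5, 0.25])
    return MSMEstimate(
        lag_ns=1.0, lag_frames=1, count_matrix=np.zeros((3, 3), dtype=int),
        transition_matrix=P, stationary=pi, active_set=np.arange(3),
        reversible=True,
    )
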