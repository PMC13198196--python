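import numpy as np
import pandas as pd
import pytest

from herdsync.scan_data import Individual, ObservationDataset, Sex
from herdsync.simulate import SimulationConfig, simulate_herd


def make_dataset(scan_specs, sexes):
    """Build a small ObservationDataset by hand.

    scan_specs: list of (session_id, scan_index, focal_id,
        {animal_id: (behavior, distance_or_None, nn_rank_or_None)}).
    sexes: mapping id -> "female"/"male".
    """
    rows = []
    for sid, idx, focal, animals in scan_specs:
        ts = pd.Timestamp("2023-03-14 10:00") + pd.Timedelta(minutes=5 * (idx - 1))
        for animal, (behavior, dist, nn) in animals.items():
            rows.append(
                {
                    "session_id": sid,
                    "scan_index": idx,
                    "timestamp": ts,
                    "focal_id": focal,
                    "animal_id": animal,
                    "behavior": behavior,
                    "distance_to_focal": dist,
                    "nn_rank": nn,
                }
            )
    df = pd.DataFrame(rows)
    df["nn_rank"] = df["nn_rank"].astype("Int64")
    roster = {i: Individual(i, Sex(s)) for i, s in sexes.items()}
    return ObservationDataset(roster, df)


def simple_scan(sid, idx, focal, behaviors, sexes=None):
    """Scan where animal k is NNk for the first three non-focal animals and
    everyone is within 3 BL."""
    animals = {}
    rank = 0
    for animal, behavior in behaviors.items():
        if animal == focal:
            animals[animal] = (behavior, None, None)
        else:
            rank += 1
            animals[animal] = (behavior, "within_3BL", rank if rank <= 3 else None)
    return (sid, idx, focal, animals)


@pytest.fixture(scope="session")
def sim_default():
    """Default-config simulated herd, shared across the suite."""
    return simulate_herd(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sim_small():
    """Reduced-size coupled herd for faster model-level tests."""
    cfg = SimulationConfig(seed=7, n_sessions=48, copy_prob=0.5, prox_decay=1.0)
    return simulate_herd(cfg)
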