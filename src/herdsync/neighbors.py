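"""Nearest-neighbor synchrony, the random-conspecific control and proximity.

The focal protocol records, at every scan, the focal animal's three nearest
neighbors (NN1-NN3) and a distance category for every other animal present.
The random conspecific is drawn after the fact with a seeded generator from
the animals present that were neither the focal nor a recorded neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scan_data import DistanceCategory, ObservationDataset

__all__ = [
    "NEIGHBOR_TYPES",
    "SessionNeighborSynchrony",
    "select_random_conspecific",
    "session_neighbor_synchrony",
    "session_table",
    "nn_scan_table",
    "dyadic_proximity_likelihood",
    "proximity_table",
]

NEIGHBOR_TYPES: tuple[str, ...] = ("NN1", "NN2", "NN3", "random_conspecific")

_CLOSE = {DistanceCategory.WITHIN_1BL.value, DistanceCategory.WITHIN_3BL.value}


@dataclass(frozen=True)
class SessionNeighborSynchrony:
    session_id: str
    focal_id: str
    n_valid: dict[str, int]  # per neighbor type
    n_sync: dict[str, int]
    proportion: dict[str, float | None]


def select_random_conspecific(scan: pd.DataFrame, rng: np.random.Generator) -> str | None:
    """Uniform draw from animals present excluding the focal and NN1-NN3.

    Returns ``None`` (with no error) when no animal is eligible.
    """
    focal = scan["focal_id"].iloc[0]
    neighbors = set(scan.loc[scan["nn_rank"].notna(), "animal_id"])
    eligible = sorted(set(scan["animal_id"]) - neighbors - {focal})
    if not eligible:
        return None
    return str(rng.choice(eligible))


def _scan_type_ids(scan: pd.DataFrame, rng: np.random.Generator) -> dict[str, str | None]:
    by_rank = {int(r): a for r, a in zip(scan["nn_rank"], scan["animal_id"]) if pd.notna(r)}
    return {
        "NN1": by_rank.get(1),
        "NN2": by_rank.get(2),
        "NN3": by_rank.get(3),
        "random_conspecific": select_random_conspecific(scan, rng),
    }


def session_neighbor_synchrony(
    session: pd.DataFrame, rng: np.random.Generator
) -> SessionNeighborSynchrony:
    """Per neighbor type, the proportion of the session's scans in which that
    type's animal matched the focal's behavior.

    Neighbor identity may change between scans; only the rank matters.  The
    denominator for a type is the number of scans where the type exists
    (normally 4); a type with zero valid scans gets proportion ``None``.
    """
    n_valid = {t: 0 for t in NEIGHBOR_TYPES}
    n_sync = {t: 0 for t in NEIGHBOR_TYPES}
    focal_id = session["focal_id"].iloc[0]
    for _, scan in session.groupby("scan_index", sort=True):
        behav = dict(zip(scan["animal_id"], scan["behavior"]))
        focal_b = behav.get(focal_id)
        if focal_b is None:
            continue
        ids = _scan_type_ids(scan, rng)
        for t, animal in ids.items():
            if animal is None or behav.get(animal) is None:
                continue
            n_valid[t] += 1
            if behav[animal] == focal_b:
                n_sync[t] += 1
    proportion = {
        t: (n_sync[t] / n_valid[t]) if n_valid[t] > 0 else None for t in NEIGHBOR_TYPES
    }
    return SessionNeighborSynchrony(
        session_id=str(session["session_id"].iloc[0]),
        focal_id=str(focal_id),
        n_valid=n_valid,
        n_sync=n_sync,
        proportion=proportion,
    )


def session_table(dataset: ObservationDataset, rng: np.random.Generator) -> pd.DataFrame:
    """Session x neighbor-type model table for the proximity-synchrony GLMM.

    Columns: session_id, focal_id, hour, neighbor_type, n_sync, n_valid,
    proportion.  Types with zero valid scans in a session are omitted.
    """
    rows = []
    for sid, session in dataset.iter_sessions():
        res = session_neighbor_synchrony(session, rng)
        hour = int(session["timestamp"].iloc[0].hour)
        for t in NEIGHBOR_TYPES:
            if res.n_valid[t] == 0:
                continue
            rows.append(
                {
                    "session_id": sid,
                    "focal_id": res.focal_id,
                    "hour": hour,
                    "neighbor_type": t,
                    "n_sync": res.n_sync[t],
                    "n_valid": res.n_valid[t],
                    "proportion": res.proportion[t],
                }
            )
    return pd.DataFrame(rows)


def nn_scan_table(
    dataset: ObservationDataset,
    affiliation: pd.DataFrame,
    ranks: pd.Series,
) -> tuple[pd.DataFrame, int]:
    """Scan-level focal/NN1 records for the binary-synchrony GLMM.

    Returns one row per scan having a recorded NN1 with known behaviors for
    both members, plus the count of skipped scans.  ``affiliation`` is the
    symmetric binary matrix; ``ranks`` maps id -> ordinal dominance rank.
    """
    sex_of = dataset.sex_of
    rows = []
    n_skipped = 0
    for (sid, idx), scan in dataset.iter_scans():
        focal = scan["focal_id"].iloc[0]
        nn1 = scan.loc[scan["nn_rank"] == 1, "animal_id"]
        behav = dict(zip(scan["animal_id"], scan["behavior"]))
        if nn1.empty or behav.get(focal) is None or behav.get(nn1.iloc[0]) is None:
            n_skipped += 1
            continue
        nn1 = nn1.iloc[0]
        dist = scan.loc[scan["animal_id"] == nn1, "distance_to_focal"].iloc[0]
        rows.append(
            {
                "session_id": sid,
                "scan_index": int(idx),
                "focal_id": focal,
                "nn1_id": nn1,
                "synchronized": int(behav[focal] == behav[nn1]),
                "sex_combo": "same" if sex_of[focal] == sex_of[nn1] else "different",
                "affiliation": int(affiliation.loc[focal, nn1]),
                "rank_diff": int(abs(ranks[focal] - ranks[nn1])),
                "distance_category": dist,
                "hour": int(scan["timestamp"].iloc[0].hour),
            }
        )
    return pd.DataFrame(rows), n_skipped


def dyadic_proximity_likelihood(dataset: ObservationDataset, pair: tuple[str, str]) -> float:
    """Proportion of focal co-presence scans in which the pair was within
    three body lengths (the within-1-BL category nests inside 3 BL)."""
    a, b = pair
    num = 0
    den = 0
    for _, scan in dataset.iter_scans():
        focal = scan["focal_id"].iloc[0]
        if focal not in (a, b):
            continue
        other = b if focal == a else a
        row = scan.loc[scan["animal_id"] == other]
        if row.empty or scan.loc[scan["animal_id"] == focal].empty:
            continue
        den += 1
        if row["distance_to_focal"].iloc[0] in _CLOSE:
            num += 1
    if den == 0:
        raise ValueError(f"pair {pair} never co-present with one member focal")
    return num / den


def proximity_table(dataset: ObservationDataset) -> pd.DataFrame:
    """Close-proximity likelihood for every dyad with >=1 focal co-presence scan."""
    ids = dataset.ids
    # accumulate counts in one pass instead of per-pair rescans
    num: dict[tuple[str, str], int] = {}
    den: dict[tuple[str, str], int] = {}
    for _, scan in dataset.iter_scans():
        focal = scan["focal_id"].iloc[0]
        if scan.loc[scan["animal_id"] == focal].empty:
            continue
        for row in scan.itertuples(index=False):
            if row.animal_id == focal:
                continue
            key = tuple(sorted((focal, row.animal_id)))
            den[key] = den.get(key, 0) + 1
            if row.distance_to_focal in _CLOSE:
                num[key] = num.get(key, 0) + 1
    rows = [
        {
            "id_a": k[0],
            "id_b": k[1],
            "n_focal_co_present": den[k],
            "proximity_likelihood": num.get(k, 0) / den[k],
        }
        for k in sorted(den)
    ]
    return pd.DataFrame(rows)
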