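"""Data model, CSV I/O and validation for instantaneous scan-sampling observations.

The canonical in-memory representation is a long-format :class:`pandas.DataFrame`
(one row per animal per scan) wrapped by :class:`ObservationDataset` together
with a sex roster.  Record-level dataclasses are provided for typed access at
the API boundary.
"""

from __future__ import annotations

import enum
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "BehaviorCategory",
    "DistanceCategory",
    "Individual",
    "ScanRecord",
    "ObservationDataset",
    "ValidationReport",
    "Violation",
    "read_scans",
    "write_scans",
    "validate",
    "group_size_summary",
    "behavior_budget",
    "BEHAVIOR_ORDER",
    "SCAN_COLUMNS",
]


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class BehaviorCategory(str, enum.Enum):
    """The four mutually exclusive activity categories."""

    LYING = "lying"
    STANDING = "standing"
    WALKING = "walking"
    FORAGING = "foraging"


#: Fixed category order used for behavior-budget vectors and kappa tables.
BEHAVIOR_ORDER: tuple[str, ...] = tuple(b.value for b in BehaviorCategory)


class DistanceCategory(str, enum.Enum):
    """Ordered proximity categories relative to the scan's focal animal.

    One body length is roughly one metre; the categories are nested, i.e.
    ``within_1BL`` implies ``within_3BL``.
    """

    WITHIN_1BL = "within_1BL"
    WITHIN_3BL = "within_3BL"
    OVER_3BL = "over_3BL"


DISTANCE_ORDER: tuple[str, ...] = tuple(d.value for d in DistanceCategory)

#: Columns of the canonical scan CSV, in order.
SCAN_COLUMNS: tuple[str, ...] = (
    "session_id",
    "scan_index",
    "timestamp",
    "focal_id",
    "animal_id",
    "sex",
    "behavior",
    "distance_to_focal",
    "nn_rank",
)


@dataclass(frozen=True)
class Individual:
    id: str
    sex: Sex


@dataclass(frozen=True)
class ScanRecord:
    """One animal's state in one instantaneous scan."""

    session_id: str
    scan_index: int
    timestamp: pd.Timestamp
    focal_id: str
    animal_id: str
    behavior: BehaviorCategory | None
    distance_to_focal: DistanceCategory | None
    nn_rank: int | None


@dataclass(frozen=True)
class Violation:
    kind: str
    session_id: str
    scan_index: int | None
    detail: str


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]

    @property
    def ok(self) -> bool:
        return len(self.violations) == 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "n_violations": len(self.violations),
                "violations": [v.__dict__ for v in self.violations],
            },
            indent=2,
        )


class ObservationDataset:
    """A roster of individuals plus a long table of scan records.

    Parameters
    ----------
    individuals
        Mapping from animal id to :class:`Individual`.
    df
        Long-format table with columns :data:`SCAN_COLUMNS` minus ``sex``
        (sex lives on the roster to prevent contradictory rows).
    incomplete_sessions
        Session ids in which at least one present animal's behavior could not
        be recorded; retained but flagged so session-level analyses can drop
        them.
    """

    def __init__(
        self,
        individuals: Mapping[str, Individual],
        df: pd.DataFrame,
        incomplete_sessions: Iterable[str] = (),
    ):
        self.individuals = dict(individuals)
        self.df = df.reset_index(drop=True)
        self.incomplete_sessions = frozenset(incomplete_sessions)
        unknown = set(df["animal_id"]) | set(df["focal_id"])
        unknown -= set(self.individuals)
        if unknown:
            raise ValueError(f"scan rows reference ids missing from roster: {sorted(unknown)}")

    # -- basic accessors ---------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return sorted(self.individuals)

    @property
    def sex_of(self) -> dict[str, str]:
        return {i: ind.sex.value for i, ind in self.individuals.items()}

    @property
    def n_animals(self) -> int:
        return len(self.individuals)

    @property
    def session_ids(self) -> list[str]:
        return list(self.df["session_id"].unique())

    @property
    def n_scans(self) -> int:
        return self.df.groupby(["session_id", "scan_index"], sort=False).ngroups

    def iter_scans(self) -> Iterator[tuple[tuple[str, int], pd.DataFrame]]:
        """Yield ((session_id, scan_index), scan sub-table) pairs."""
        yield from self.df.groupby(["session_id", "scan_index"], sort=False)

    def iter_sessions(self) -> Iterator[tuple[str, pd.DataFrame]]:
        yield from self.df.groupby("session_id", sort=False)

    def iter_records(self) -> Iterator[ScanRecord]:
        for row in self.df.itertuples(index=False):
            yield ScanRecord(
                session_id=row.session_id,
                scan_index=int(row.scan_index),
                timestamp=row.timestamp,
                focal_id=row.focal_id,
                animal_id=row.animal_id,
                behavior=None if row.behavior is None else BehaviorCategory(row.behavior),
                distance_to_focal=(
                    None if row.distance_to_focal is None else DistanceCategory(row.distance_to_focal)
                ),
                nn_rank=None if pd.isna(row.nn_rank) else int(row.nn_rank),
            )

    def subset(self, mask: pd.Series | np.ndarray) -> "ObservationDataset":
        """Row-subset sharing the same roster (used by the activity filter)."""
        sub = self.df.loc[mask]
        return ObservationDataset(self.individuals, sub, self.incomplete_sessions & set(sub["session_id"]))

    def drop_incomplete_sessions(self) -> "ObservationDataset":
        if not self.incomplete_sessions:
            return self
        keep = ~self.df["session_id"].isin(self.incomplete_sessions)
        return ObservationDataset(self.individuals, self.df.loc[keep], ())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ObservationDataset({self.n_animals} animals, "
            f"{len(self.session_ids)} sessions, {self.n_scans} scans)"
        )


def _normalize_behavior(value: object, row_no: int) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    text = str(value).strip().lower()
    if text not in BEHAVIOR_ORDER:
        raise ValueError(
            f"row {row_no}: unknown behavior {value!r}; accepted labels are {list(BEHAVIOR_ORDER)}"
        )
    return text


def _normalize_distance(value: object, row_no: int) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    text = str(value).strip()
    lowered = {d.lower(): d for d in DISTANCE_ORDER}
    if text.lower() not in lowered:
        raise ValueError(
            f"row {row_no}: unknown distance category {value!r}; accepted: {list(DISTANCE_ORDER)}"
        )
    return lowered[text.lower()]


def read_scans(
    path,
    id_roster: Mapping[str, str | Sex] | None = None,
    column_map: Mapping[str, str] | None = None,
    allow_incomplete: bool = False,
) -> ObservationDataset:
    """Read a long-format scan CSV into a typed :class:`ObservationDataset`.

    Parameters
    ----------
    path
        CSV with header and columns :data:`SCAN_COLUMNS` (``sex`` may be
        omitted when ``id_roster`` supplies it).
    id_roster
        Optional mapping id -> sex overriding/replacing the ``sex`` column.
    column_map
        Optional rename map applied first, for foreign export dialects
        (e.g. ZooMonitor column names).
    allow_incomplete
        When true, rows with a missing behavior are kept (behavior ``None``)
        and their sessions flagged; otherwise a missing behavior is an error.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing_cols = {"session_id", "scan_index", "timestamp", "focal_id", "animal_id", "behavior"} - set(
        raw.columns
    )
    if missing_cols:
        raise ValueError(f"scan CSV missing required columns: {sorted(missing_cols)}")

    behaviors = []
    incomplete_sessions: set[str] = set()
    for i, v in enumerate(raw["behavior"].tolist()):
        b = _normalize_behavior(v, i + 2)  # +2: header + 1-based
        if b is None:
            if not allow_incomplete:
                raise ValueError(f"row {i + 2}: missing behavior (pass allow_incomplete=True to keep)")
            incomplete_sessions.add(raw["session_id"].iloc[i])
        behaviors.append(b)

    distances = [
        _normalize_distance(v, i + 2)
        for i, v in enumerate(raw.get("distance_to_focal", pd.Series([""] * len(raw))).tolist())
    ]

    nn_raw = raw.get("nn_rank", pd.Series([""] * len(raw)))
    nn_rank = pd.array([int(v) if str(v).strip() not in ("", "nan") else pd.NA for v in nn_raw], dtype="Int64")
    bad_nn = [(i + 2, v) for i, v in enumerate(nn_rank) if v is not pd.NA and not 1 <= v <= 3]
    if bad_nn:
        raise ValueError(f"nn_rank outside 1-3 at rows {[r for r, _ in bad_nn]}")

    df = pd.DataFrame(
        {
            "session_id": raw["session_id"].astype(str),
            "scan_index": raw["scan_index"].astype(int),
            "timestamp": pd.to_datetime(raw["timestamp"]),
            "focal_id": raw["focal_id"].astype(str),
            "animal_id": raw["animal_id"].astype(str),
            "behavior": behaviors,
            "distance_to_focal": distances,
            "nn_rank": nn_rank,
        }
    )

    dup = df.duplicated(subset=["session_id", "scan_index", "animal_id"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ValueError(
            "duplicate record: animal "
            f"{first.animal_id!r} appears more than once in scan ({first.session_id!r}, {first.scan_index})"
        )

    roster: dict[str, Individual] = {}
    if id_roster is not None:
        roster = {str(i): Individual(str(i), Sex(str(s))) for i, s in id_roster.items()}
    elif "sex" in raw.columns:
        for animal, sex in zip(raw["animal_id"], raw["sex"]):
            sex_e = Sex(str(sex).strip().lower())
            prev = roster.get(str(animal))
            if prev is not None and prev.sex is not sex_e:
                raise ValueError(f"contradictory sex entries for animal {animal!r}")
            roster[str(animal)] = Individual(str(animal), sex_e)
    else:
        raise ValueError("no sex information: provide an id_roster or a 'sex' column")

    return ObservationDataset(roster, df, incomplete_sessions)


def write_scans(dataset: ObservationDataset, path) -> None:
    """Write the canonical CSV (inverse of :func:`read_scans`)."""
    out = dataset.df.copy()
    out["sex"] = out["animal_id"].map(dataset.sex_of)
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%d %H:%M")
    out[list(SCAN_COLUMNS)].to_csv(path, index=False)


def validate(dataset: ObservationDataset) -> ValidationReport:
    """Report per-scan invariant violations without raising.

    Checks: the focal animal appears in its own scan with null distance and
    null nn_rank, nn_rank values are unique within a scan, and flagged
    incomplete sessions are surfaced.
    """
    violations: list[Violation] = []
    for (sid, idx), scan in dataset.iter_scans():
        focal = scan["focal_id"].iloc[0]
        focal_rows = scan[scan["animal_id"] == focal]
        if focal_rows.empty:
            violations.append(Violation("missing_focal", sid, int(idx), f"focal {focal!r} absent from scan"))
        else:
            if focal_rows["distance_to_focal"].notna().any():
                violations.append(
                    Violation("focal_distance_nonnull", sid, int(idx), f"focal {focal!r} has a distance category")
                )
            if focal_rows["nn_rank"].notna().any():
                violations.append(
                    Violation("focal_nn_rank_nonnull", sid, int(idx), f"focal {focal!r} has an nn_rank")
                )
        ranks = scan["nn_rank"].dropna()
        if ranks.duplicated().any():
            dupes = sorted(ranks[ranks.duplicated()].unique().tolist())
            violations.append(Violation("duplicate_nn", sid, int(idx), f"duplicate nn_rank values {dupes}"))
        if scan["focal_id"].nunique() > 1:
            violations.append(Violation("multiple_focals", sid, int(idx), "more than one focal id in scan"))
    for sid in sorted(dataset.incomplete_sessions):
        violations.append(Violation("incomplete_session", sid, None, "missing behavior for >=1 present animal"))
    return ValidationReport(tuple(violations))


def group_size_summary(dataset: ObservationDataset) -> dict[str, float]:
    """Mean / min / max / sd of the number of animals present per scan."""
    if dataset.df.empty:
        raise ValueError("cannot summarise group size of an empty dataset")
    sizes = dataset.df.groupby(["session_id", "scan_index"], sort=False)["animal_id"].nunique()
    return {
        "mean": float(sizes.mean()),
        "min": int(sizes.min()),
        "max": int(sizes.max()),
        "sd": float(sizes.std(ddof=1)) if len(sizes) > 1 else 0.0,
        "n_scans": int(len(sizes)),
    }


def behavior_budget(dataset: ObservationDataset) -> pd.DataFrame:
    """Per-individual behavior proportions.

    Returns a frame indexed by animal id with one column per behavior in
    :data:`BEHAVIOR_ORDER`; each row sums to 1.  Individuals never observed
    are excluded with a warning.
    """
    obs = dataset.df.dropna(subset=["behavior"])
    counts = (
        obs.groupby(["animal_id", "behavior"], sort=False).size().unstack(fill_value=0)
    )
    for b in BEHAVIOR_ORDER:
        if b not in counts.columns:
            counts[b] = 0
    counts = counts[list(BEHAVIOR_ORDER)]
    unseen = sorted(set(dataset.individuals) - set(counts.index))
    if unseen:
        warnings.warn(f"individuals never observed, excluded from budget: {unseen}", stacklevel=2)
    budget = counts.div(counts.sum(axis=1), axis=0)
    return budget.sort_index()
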