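"""Foraging-activity threshold filtering.

High-foraging scans can synchronize the whole group through a shared
environmental driver rather than social coupling, so downstream dyadic and
neighbor analyses are re-run on a low-foraging subset.  Inclusion is strict:
a scan is retained iff its foraging fraction is *below* the threshold; scans
at or above it are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scan_data import BehaviorCategory, ObservationDataset

__all__ = [
    "scan_foraging_fraction",
    "per_scan_foraging",
    "filter_scans",
    "filter_sessions",
    "suggest_threshold",
]

_FORAGING = BehaviorCategory.FORAGING.value


def scan_foraging_fraction(scan: pd.DataFrame) -> float:
    """Fraction of animals present in one scan that are foraging."""
    if len(scan) == 0:
        raise ValueError("empty scan")
    return float((scan["behavior"] == _FORAGING).sum() / len(scan))


def per_scan_foraging(dataset: ObservationDataset) -> pd.Series:
    """Foraging fraction per scan, indexed by (session_id, scan_index)."""
    g = dataset.df.groupby(["session_id", "scan_index"], sort=False)["behavior"]
    return g.apply(lambda s: float((s == _FORAGING).sum() / len(s)))


def filter_scans(
    dataset: ObservationDataset, threshold: float = 0.80
) -> tuple[ObservationDataset, int]:
    """Retain scans whose foraging fraction is strictly below ``threshold``.

    Returns the retained subset and the number of excluded scans.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    fractions = per_scan_foraging(dataset)
    passing = fractions[fractions < threshold]
    keys = pd.MultiIndex.from_frame(dataset.df[["session_id", "scan_index"]])
    mask = keys.isin(passing.index)
    retained = dataset.subset(mask)
    return retained, int((fractions >= threshold).sum())


def filter_sessions(
    dataset: ObservationDataset, threshold: float = 0.80
) -> tuple[ObservationDataset, int]:
    """Retain whole sessions in which *every* scan passes the scan filter."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    fractions = per_scan_foraging(dataset)
    max_by_session = fractions.groupby(level="session_id").max()
    ok_sessions = set(max_by_session[max_by_session < threshold].index)
    mask = dataset.df["session_id"].isin(ok_sessions)
    retained = dataset.subset(mask)
    n_excluded = int(len(max_by_session) - len(ok_sessions))
    return retained, n_excluded


def suggest_threshold(dataset: ObservationDataset, k: float = 0.5) -> dict:
    """Advisory moments of the per-scan foraging fractions.

    Returns the mean, sample sd, the mean + k*sd offset, and 10-bin histogram
    counts.  No threshold is applied automatically; the offset is a diagnostic
    to be read alongside the histogram.
    """
    fractions = per_scan_foraging(dataset)
    if len(fractions) < 2:
        raise ValueError("need >=2 scans to compute a spread")
    mean = float(fractions.mean())
    sd = float(fractions.std(ddof=1))
    counts, edges = np.histogram(fractions.to_numpy(), bins=10, range=(0.0, 1.0))
    return {
        "mean": mean,
        "sd": sd,
        "offset": mean + k * sd,
        "k": k,
        "histogram_counts": counts.tolist(),
        "histogram_edges": edges.tolist(),
    }
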