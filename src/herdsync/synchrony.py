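"""Group- and dyad-level synchrony statistics.

Implements the per-scan group synchrony degree (modal-behavior percentage),
cumulative threshold proportions, the Fleiss (1971) multi-rater agreement
coefficient over complete scans, observed dyadic synchrony, the
independence-null expected synchrony, and the paired observed-vs-expected
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scan_data import BEHAVIOR_ORDER, ObservationDataset, behavior_budget

__all__ = [
    "GroupSynchronyResult",
    "KappaResult",
    "group_synchrony_degree",
    "per_scan_degrees",
    "group_synchrony_summary",
    "fleiss_kappa",
    "behavior_profiles",
    "expected_synchrony",
    "dyadic_observed_synchrony",
    "dyad_synchrony_table",
    "observed_vs_expected_test",
]


@dataclass(frozen=True)
class GroupSynchronyResult:
    degrees: pd.Series  # per-scan degree in percent, indexed by (session, scan)
    mean: float
    sd: float
    min: float
    max: float
    threshold_props: dict[int, float]  # threshold(%) -> cumulative proportion of scans


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    n_subjects: int
    n_raters: int
    n_categories: int
    p_bar: float
    p_bar_e: float


def group_synchrony_degree(scan: pd.DataFrame) -> float:
    """Percentage of animals in one scan performing the most common behavior."""
    if len(scan) == 0:
        raise ValueError("empty scan")
    counts = scan["behavior"].value_counts()
    return float(100.0 * counts.iloc[0] / len(scan))


def per_scan_degrees(dataset: ObservationDataset) -> pd.Series:
    g = dataset.df.groupby(["session_id", "scan_index"], sort=False)["behavior"]
    return g.apply(lambda s: float(100.0 * s.value_counts().iloc[0] / len(s)))


def group_synchrony_summary(
    dataset: ObservationDataset, thresholds: tuple[int, ...] = (70, 90, 100)
) -> GroupSynchronyResult:
    """Mean/sd/range of per-scan synchrony degrees plus cumulative threshold
    proportions (a scan at 100% counts toward every lower threshold)."""
    degrees = per_scan_degrees(dataset)
    if degrees.empty:
        raise ValueError("no scans")
    props = {int(t): float((degrees >= t).mean()) for t in thresholds}
    return GroupSynchronyResult(
        degrees=degrees,
        mean=float(degrees.mean()),
        sd=float(degrees.std(ddof=1)) if len(degrees) > 1 else 0.0,
        min=float(degrees.min()),
        max=float(degrees.max()),
        threshold_props=props,
    )


def _complete_scan_table(dataset: ObservationDataset) -> pd.DataFrame:
    """Subject x category count table over scans where all roster animals are present."""
    roster_n = dataset.n_animals
    rows = []
    for key, scan in dataset.iter_scans():
        if scan["animal_id"].nunique() == roster_n and scan["behavior"].notna().all():
            counts = scan["behavior"].value_counts()
            rows.append([int(counts.get(b, 0)) for b in BEHAVIOR_ORDER])
    return pd.DataFrame(rows, columns=list(BEHAVIOR_ORDER))


def fleiss_kappa(dataset: ObservationDataset, require_all: bool = True) -> KappaResult:
    """Fleiss (1971) agreement with animals as raters and scans as subjects.

    Only scans where every roster individual is present enter the computation
    (the workaround for fluctuating group membership); ``require_all=False``
    is deliberately not offered a padded alternative and simply relaxes the
    presence requirement to "constant group size equal to the first scan".
    """
    if require_all:
        table = _complete_scan_table(dataset)
    else:
        sizes = dataset.df.groupby(["session_id", "scan_index"], sort=False)["animal_id"].nunique()
        m = int(sizes.iloc[0])
        rows = []
        for key, scan in dataset.iter_scans():
            if len(scan) == m:
                counts = scan["behavior"].value_counts()
                rows.append([int(counts.get(b, 0)) for b in BEHAVIOR_ORDER])
        table = pd.DataFrame(rows, columns=list(BEHAVIOR_ORDER))
    if len(table) < 2:
        raise ValueError(f"need >=2 complete scans for kappa, found {len(table)}")
    return fleiss_kappa_from_table(table.to_numpy())


def fleiss_kappa_from_table(counts: np.ndarray) -> KappaResult:
    """Kappa from a subjects x categories assignment-count matrix."""
    counts = np.asarray(counts, dtype=float)
    n_subjects, n_categories = counts.shape
    m = counts.sum(axis=1)
    if not np.all(m == m[0]):
        raise ValueError("all subjects must have the same number of raters")
    m0 = float(m[0])
    if m0 < 2:
        raise ValueError("need >=2 raters")
    p_i = ((counts**2).sum(axis=1) - m0) / (m0 * (m0 - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / counts.sum()
    p_bar_e = float((p_j**2).sum())
    if p_bar_e >= 1.0:
        raise ValueError("all assignments fall in one category; kappa is undefined (P_e = 1)")
    kappa = (p_bar - p_bar_e) / (1.0 - p_bar_e)
    return KappaResult(
        kappa=float(kappa),
        n_subjects=int(n_subjects),
        n_raters=int(m0),
        n_categories=int(n_categories),
        p_bar=p_bar,
        p_bar_e=p_bar_e,
    )


def behavior_profiles(dataset: ObservationDataset) -> pd.DataFrame:
    """Per-individual 4-vector of behavior proportions (rows sum to 1)."""
    return behavior_budget(dataset)


def expected_synchrony(p_a: np.ndarray | pd.Series, p_b: np.ndarray | pd.Series) -> float:
    """Chance-match probability of two independently behaving animals:
    sum over the four behaviors of the product of their proportions."""
    a = np.asarray(p_a, dtype=float)
    b = np.asarray(p_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    return float(np.dot(a, b))


def _presence_and_behavior(dataset: ObservationDataset):
    """Wide (scan x animal) behavior matrix as integer codes; -1 = absent."""
    code = {b: i for i, b in enumerate(BEHAVIOR_ORDER)}
    df = dataset.df
    wide = (
        df.assign(bcode=df["behavior"].map(code))
        .pivot_table(
            index=["session_id", "scan_index"],
            columns="animal_id",
            values="bcode",
            aggfunc="first",
        )
        .reindex(columns=dataset.ids)
    )
    mat = wide.to_numpy()
    mat = np.where(np.isnan(mat), -1, mat).astype(int)
    return mat, list(wide.columns), wide.index


def dyadic_observed_synchrony(dataset: ObservationDataset, pair: tuple[str, str]) -> dict:
    """Observed synchrony for one unordered pair over all scans of the dataset."""
    a, b = pair
    mat, ids, _ = _presence_and_behavior(dataset)
    ia, ib = ids.index(a), ids.index(b)
    co = (mat[:, ia] >= 0) & (mat[:, ib] >= 0)
    n_co = int(co.sum())
    if n_co == 0:
        raise ValueError(f"pair {pair} never co-present")
    matches = int((mat[co, ia] == mat[co, ib]).sum())
    return {"id_a": a, "id_b": b, "n_co_present": n_co, "observed": matches / n_co}


def dyad_synchrony_table(dataset: ObservationDataset) -> pd.DataFrame:
    """Observed and expected synchrony for every unordered pair of roster ids.

    Pairs never co-present are excluded.  Expected synchrony uses each
    animal's all-scan behavior profile.
    """
    mat, ids, _ = _presence_and_behavior(dataset)
    profiles = behavior_profiles(dataset)
    present = mat >= 0
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            co = present[:, i] & present[:, j]
            n_co = int(co.sum())
            if n_co == 0:
                continue
            observed = float((mat[co, i] == mat[co, j]).mean())
            exp = expected_synchrony(profiles.loc[ids[i]], profiles.loc[ids[j]])
            rows.append(
                {
                    "id_a": ids[i],
                    "id_b": ids[j],
                    "n_co_present": n_co,
                    "observed": observed,
                    "expected": exp,
                }
            )
    return pd.DataFrame(rows)


def observed_vs_expected_test(dyads: pd.DataFrame) -> dict:
    """Two-sided paired t-test of observed vs expected dyadic synchrony."""
    if len(dyads) < 2:
        raise ValueError("need >=2 dyads")
    diffs = dyads["observed"].to_numpy() - dyads["expected"].to_numpy()
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise ValueError("zero variance of observed - expected differences")
    res = stats.ttest_rel(dyads["observed"], dyads["expected"])
    return {
        "t": float(res.statistic),
        "df": int(len(dyads) - 1),
        "p": float(res.pvalue),
        "mean_observed": float(dyads["observed"].mean()),
        "mean_expected": float(dyads["expected"].mean()),
    }
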