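"""Affiliation, winner-loser matrices and randomized-Elo dominance ranking.

Allogrooming events define a binary, symmetric dyadic affiliation.
Displacement events (actor = winner, recipient = loser) are expanded into a
sequence whose order is shuffled many times; sequential Elo updates are
applied per shuffle and scores averaged over shuffles, removing order
effects.  Ordinal ranks (1 = most dominant) are the downstream contract;
absolute scores depend on the Elo constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DominanceResult",
    "read_interactions",
    "build_affiliation",
    "build_winner_loser",
    "events_from_matrix",
    "randomized_elo",
    "ranks_and_covariates",
]

INTERACTION_KINDS = ("allogrooming", "displacement")


@dataclass(frozen=True)
class DominanceResult:
    scores: pd.Series  # mean randomized-Elo score per id
    ranks: pd.Series  # ordinal rank 1..N, 1 = highest mean score
    n_randomizations: int
    k_factor: float
    initial_score: float
    tied_ids: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.scores, "rank": self.ranks})


def read_interactions(path, roster: set[str] | None = None) -> pd.DataFrame:
    """Read an interaction CSV (timestamp, actor, recipient, kind)."""
    df = pd.read_csv(path, dtype=str)
    required = {"actor", "recipient", "kind"}
    if missing := required - set(df.columns):
        raise ValueError(f"interaction CSV missing columns: {sorted(missing)}")
    bad_kind = set(df["kind"]) - set(INTERACTION_KINDS)
    if bad_kind:
        raise ValueError(f"unknown interaction kinds {sorted(bad_kind)}; accepted: {INTERACTION_KINDS}")
    if (df["actor"] == df["recipient"]).any():
        raise ValueError("self-directed interaction (actor == recipient)")
    if roster is not None:
        unknown = (set(df["actor"]) | set(df["recipient"])) - set(roster)
        if unknown:
            raise ValueError(f"interaction ids missing from roster: {sorted(unknown)}")
    return df


def _check_ids(events: pd.DataFrame, roster: list[str]) -> None:
    unknown = (set(events["actor"]) | set(events["recipient"])) - set(roster)
    if unknown:
        raise ValueError(f"unknown ids in events: {sorted(unknown)}")


def build_affiliation(events: pd.DataFrame, roster: list[str]) -> pd.DataFrame:
    """Symmetric binary matrix: 1 iff the pair ever exchanged allogrooming."""
    groom = events[events["kind"] == "allogrooming"] if "kind" in events.columns else events
    if len(groom):
        _check_ids(groom, roster)
    mat = pd.DataFrame(0, index=roster, columns=roster, dtype=int)
    for row in groom.itertuples(index=False):
        mat.loc[row.actor, row.recipient] = 1
        mat.loc[row.recipient, row.actor] = 1
    np.fill_diagonal(mat.values, 0)
    return mat


def build_winner_loser(events: pd.DataFrame, roster: list[str]) -> pd.DataFrame:
    """Count matrix W[i, j] = number of times i displaced j."""
    disp = events[events["kind"] == "displacement"] if "kind" in events.columns else events
    if len(disp):
        _check_ids(disp, roster)
    mat = pd.DataFrame(0, index=roster, columns=roster, dtype=int)
    for row in disp.itertuples(index=False):
        mat.loc[row.actor, row.recipient] += 1
    return mat


def events_from_matrix(w: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Expand a winner-loser count matrix to (winner_idx, loser_idx) arrays."""
    roster = list(w.index)
    winners, losers = [], []
    arr = w.to_numpy()
    for i in range(len(roster)):
        for j in range(len(roster)):
            winners.extend([i] * int(arr[i, j]))
            losers.extend([j] * int(arr[i, j]))
    return np.asarray(winners, dtype=int), np.asarray(losers, dtype=int), roster


def randomized_elo(
    w: pd.DataFrame,
    n_rand: int = 10_000,
    k_factor: float = 200.0,
    initial_score: float = 1000.0,
    seed: int | np.random.Generator = 0,
) -> DominanceResult:
    """Randomized Elo scores and ordinal ranks from a winner-loser matrix.

    For each of ``n_rand`` replicates the event list is uniformly shuffled and
    sequential Elo updates applied with expected win probability
    ``1 / (1 + 10 ** ((R_loser - R_winner) / 400))``; the winner gains and the
    loser loses ``k_factor * (1 - E_w)``.  Final scores are replicate means;
    ranks are by descending mean score, ties broken lexicographically by id
    and flagged.  Individuals with no interactions keep the initial score.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    winners, losers, roster = events_from_matrix(w)
    n_events = len(winners)
    if n_events == 0:
        raise ValueError("no displacement events; dominance is undefined")
    n = len(roster)

    # replicates run side by side: scores is (n_rand, n); per event step each
    # replicate applies its own (winner, loser) drawn from its permutation
    order = np.argsort(rng.random((n_rand, n_events)), axis=1)
    perm_w = winners[order]  # (n_rand, n_events)
    perm_l = losers[order]
    scores = np.full((n_rand, n), float(initial_score))
    rows = np.arange(n_rand)
    for t in range(n_events):
        wi = perm_w[:, t]
        li = perm_l[:, t]
        rw = scores[rows, wi]
        rl = scores[rows, li]
        e_w = 1.0 / (1.0 + 10.0 ** ((rl - rw) / 400.0))
        delta = k_factor * (1.0 - e_w)
        scores[rows, wi] = rw + delta
        scores[rows, li] = rl - delta

    mean_scores = pd.Series(scores.mean(axis=0), index=roster)
    # descending score, id as deterministic tie-break
    ordering = sorted(roster, key=lambda i: (-mean_scores[i], i))
    ranks = pd.Series({ind: r + 1 for r, ind in enumerate(ordering)}, dtype=int).reindex(roster)
    dup = mean_scores.round(12).duplicated(keep=False)
    tied = tuple(sorted(mean_scores.index[dup])) if dup.any() else ()
    return DominanceResult(
        scores=mean_scores,
        ranks=ranks,
        n_randomizations=int(n_rand),
        k_factor=float(k_factor),
        initial_score=float(initial_score),
        tied_ids=tied,
    )


def ranks_and_covariates(dom: DominanceResult, sex_of: dict[str, str]) -> pd.DataFrame:
    """Per-dyad covariates: absolute ordinal rank difference and sex combination."""
    ids = sorted(dom.ranks.index)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            rows.append(
                {
                    "id_a": a,
                    "id_b": b,
                    "rank_diff": int(abs(dom.ranks[a] - dom.ranks[b])),
                    "sex_combo": "same" if sex_of[a] == sex_of[b] else "different",
                }
            )
    return pd.DataFrame(rows)
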