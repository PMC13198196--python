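"""Headline summary statistics for a scan dataset.

Collects, in one dictionary, the descriptive quantities the analysis is
judged on: group synchrony degree and threshold proportions, Fleiss kappa on
complete scans, foraging-filter counts at the 80% threshold, dyadic
observed/expected synchrony means, the session-level NN1 synchrony mean, the
individual foraging-time mean and the mean group size.  Percentages are
reported on the 0-100 scale.
"""

from __future__ import annotations

import numpy as np

from .activity_filter import filter_scans, filter_sessions
from .neighbors import session_table
from .scan_data import ObservationDataset, behavior_budget, group_size_summary
from .synchrony import dyad_synchrony_table, fleiss_kappa, group_synchrony_summary

__all__ = ["headline_statistics"]


def headline_statistics(
    dataset: ObservationDataset, foraging_threshold: float = 0.80
) -> dict[str, dict]:
    """Compute the headline statistics; each entry is {'value', 'n'}."""
    out: dict[str, dict] = {}

    gs = group_synchrony_summary(dataset)
    n_scans = int(len(gs.degrees))
    out["group_synchrony_mean_pct"] = {"value": float(gs.mean), "n": n_scans}
    out["sync_ge_70_pct"] = {"value": 100.0 * gs.threshold_props[70], "n": n_scans}
    out["sync_ge_90_pct"] = {"value": 100.0 * gs.threshold_props[90], "n": n_scans}
    out["sync_eq_100_pct"] = {"value": 100.0 * gs.threshold_props[100], "n": n_scans}

    try:
        kap = fleiss_kappa(dataset)
        out["fleiss_kappa"] = {"value": float(kap.kappa), "n": int(kap.n_subjects)}
    except ValueError:
        pass  # too few complete scans

    _, n_excluded = filter_scans(dataset, foraging_threshold)
    retained_sessions, _ = filter_sessions(dataset, foraging_threshold)
    out["scans_excluded_at_80"] = {"value": float(n_excluded), "n": n_scans}
    out["sessions_retained_at_80"] = {
        "value": float(len(retained_sessions.session_ids)),
        "n": len(dataset.session_ids),
    }

    dyads = dyad_synchrony_table(dataset)
    out["dyadic_observed_mean_pct"] = {
        "value": 100.0 * float(dyads["observed"].mean()),
        "n": int(len(dyads)),
    }
    out["dyadic_expected_mean_pct"] = {
        "value": 100.0 * float(dyads["expected"].mean()),
        "n": int(len(dyads)),
    }

    # NN1 synchrony is deterministic (no random-conspecific draw involved)
    st = session_table(dataset, np.random.default_rng(0))
    nn1 = st.loc[st["neighbor_type"] == "NN1", "proportion"]
    out["nn1_mean_sync_prop"] = {"value": float(nn1.mean()), "n": int(len(nn1))}

    budget = behavior_budget(dataset)
    out["foraging_mean_pct"] = {
        "value": 100.0 * float(budget["foraging"].mean()),
        "n": int(len(budget)),
    }

    sizes = group_size_summary(dataset)
    out["group_size_mean"] = {"value": float(sizes["mean"]), "n": int(sizes["n_scans"])}
    return out
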