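"""End-to-end orchestration: filters -> synchrony metrics -> dominance ->
model tables -> regression fits, with a reproducibility manifest.

Two independent RNG streams are used (random-conspecific sampling and the
Elo randomization) so one can be varied without disturbing the other.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity_filter import filter_scans, filter_sessions, suggest_threshold
from .neighbors import nn_scan_table, proximity_table, session_table
from .scan_data import ObservationDataset, behavior_budget, group_size_summary, validate
from .simulate import SimulationConfig, simulate_herd, truth_report
from .social import build_affiliation, build_winner_loser, randomized_elo, ranks_and_covariates
from .synchrony import dyad_synchrony_table, fleiss_kappa, group_synchrony_summary, observed_vs_expected_test

logger = logging.getLogger(__name__)

__all__ = ["run_analysis", "run_end_to_end_check"]


def _dyad_table_with_covariates(dataset: ObservationDataset, dom, affiliation) -> pd.DataFrame:
    dyads = dyad_synchrony_table(dataset)
    cov = ranks_and_covariates(dom, dataset.sex_of)
    merged = dyads.merge(cov, on=["id_a", "id_b"], how="left")
    merged["affiliation"] = [
        int(affiliation.loc[a, b]) for a, b in zip(merged["id_a"], merged["id_b"])
    ]
    prox = proximity_table(dataset)
    merged = merged.merge(
        prox[["id_a", "id_b", "proximity_likelihood"]], on=["id_a", "id_b"], how="left"
    )
    return merged


def run_analysis(
    dataset: ObservationDataset,
    interactions: pd.DataFrame,
    out_dir: str | Path | None = None,
    foraging_threshold: float = 0.80,
    seed_conspecific: int = 1,
    seed_elo: int = 2,
    n_elo_randomizations: int = 10_000,
    fit_models: bool = True,
) -> dict:
    """Run the full analysis and return (optionally write) the report bundle.

    The bundle carries both the full-data and the foraging-filtered variants
    of the neighbor and dyadic analyses.  Validation failures abort.
    """
    report = validate(dataset)
    if not report.ok:
        raise ValueError(f"dataset failed validation:\n{report.to_json()}")
    dataset = dataset.drop_incomplete_sessions()

    bundle: dict = {"validation": report}
    bundle["group_size"] = group_size_summary(dataset)
    bundle["behavior_budget"] = behavior_budget(dataset)
    bundle["group_synchrony"] = group_synchrony_summary(dataset)
    bundle["foraging_diagnostic"] = suggest_threshold(dataset)

    scans_kept, n_scans_excluded = filter_scans(dataset, foraging_threshold)
    sessions_kept, n_sessions_excluded = filter_sessions(dataset, foraging_threshold)
    bundle["filter"] = {
        "threshold": foraging_threshold,
        "n_scans_total": dataset.n_scans,
        "n_scans_excluded": n_scans_excluded,
        "n_sessions_total": len(dataset.session_ids),
        "n_sessions_retained": len(sessions_kept.session_ids),
        "n_sessions_excluded": n_sessions_excluded,
    }
    bundle["group_synchrony_filtered"] = (
        group_synchrony_summary(sessions_kept) if sessions_kept.n_scans else None
    )

    try:
        bundle["fleiss_kappa"] = fleiss_kappa(dataset)
    except ValueError as exc:
        bundle["fleiss_kappa"] = None
        bundle["fleiss_kappa_note"] = str(exc)

    # social covariates
    have_interactions = interactions is not None and len(interactions) > 0
    if have_interactions:
        roster = dataset.ids
        affiliation = build_affiliation(interactions, roster)
        w = build_winner_loser(interactions, roster)
        dom = randomized_elo(w, n_rand=n_elo_randomizations, seed=seed_elo)
        bundle["affiliation"] = affiliation
        bundle["dominance"] = dom

        dyads = _dyad_table_with_covariates(dataset, dom, affiliation)
        bundle["dyads"] = dyads
        bundle["observed_vs_expected"] = observed_vs_expected_test(dyads)
        dyads_filtered = (
            _dyad_table_with_covariates(scans_kept, dom, affiliation)
            if scans_kept.n_scans
            else None
        )
        bundle["dyads_filtered"] = dyads_filtered
    else:
        logger.warning("no interaction events: affiliation/dominance analyses skipped")
        bundle["skipped"] = ["affiliation", "dominance", "dyadic models", "nn scan model"]

    rng_cons = np.random.default_rng(seed_conspecific)
    bundle["session_table"] = session_table(dataset, rng_cons)
    bundle["session_table_filtered"] = (
        session_table(sessions_kept, np.random.default_rng(seed_conspecific))
        if sessions_kept.n_scans
        else None
    )
    if have_interactions:
        nn_table, n_skipped = nn_scan_table(dataset, affiliation, dom.ranks)
        bundle["nn_scan_table"] = nn_table
        bundle["nn_scan_skipped"] = n_skipped
        if scans_kept.n_scans:
            bundle["nn_scan_table_filtered"], _ = nn_scan_table(scans_kept, affiliation, dom.ranks)

    if fit_models:
        from . import models as m

        fits: dict = {}
        if have_interactions:
            budget = behavior_budget(dataset)
            foraging = pd.DataFrame(
                {
                    "animal_id": budget.index,
                    "foraging_prop": budget["foraging"].to_numpy(),
                    "sex": [dataset.sex_of[i] for i in budget.index],
                    "rank": [int(dom.ranks[i]) for i in budget.index],
                }
            )
            fits["foraging"] = m.fit_foraging_model(foraging)
            fits["dyadic_synchrony"] = m.fit_dyadic_lmm(dyads, "observed")
            fits["dyadic_proximity"] = m.fit_dyadic_lmm(dyads, "proximity_likelihood")
            if dyads_filtered is not None and len(dyads_filtered) >= 4:
                fits["dyadic_synchrony_filtered"] = m.fit_dyadic_lmm(dyads_filtered, "observed")
            glmm_tables = [bundle["session_table"], ]
            glmm_names = ["neighbor"]
            if bundle["session_table_filtered"] is not None and len(bundle["session_table_filtered"]):
                glmm_tables.append(bundle["session_table_filtered"])
                glmm_names.append("neighbor_filtered")
            glmm_fits = m.fit_neighbor_models(glmm_tables)
            fits.update(dict(zip(glmm_names, glmm_fits)))
            fits["nn_scan"] = m.fit_nn_scan_model(nn_table)
        else:
            fits["neighbor"] = m.fit_neighbor_model(bundle["session_table"])
        bundle["model_fits"] = fits

    bundle["manifest"] = {
        "package_version": __version__,
        "seed_conspecific": seed_conspecific,
        "seed_elo": seed_elo,
        "n_elo_randomizations": n_elo_randomizations,
        "foraging_threshold": foraging_threshold,
        "n_scan_rows": int(len(dataset.df)),
        "scan_data_sha256": hashlib.sha256(
            pd.util.hash_pandas_object(dataset.df.astype(str)).to_numpy().tobytes()
        ).hexdigest(),
    }

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "validation.json").write_text(bundle["validation"].to_json())
    summary: dict = {
        "group_size": bundle["group_size"],
        "filter": bundle["filter"],
        "manifest": bundle["manifest"],
    }
    gs = bundle["group_synchrony"]
    summary["group_synchrony"] = {
        "mean": gs.mean,
        "sd": gs.sd,
        "min": gs.min,
        "max": gs.max,
        "threshold_props": gs.threshold_props,
    }
    if bundle.get("fleiss_kappa") is not None:
        k = bundle["fleiss_kappa"]
        summary["fleiss_kappa"] = {
            "kappa": k.kappa,
            "n_subjects": k.n_subjects,
            "n_raters": k.n_raters,
        }
    else:
        summary["fleiss_kappa"] = None
        summary["fleiss_kappa_note"] = bundle.get("fleiss_kappa_note")
    if "observed_vs_expected" in bundle:
        summary["observed_vs_expected"] = bundle["observed_vs_expected"]
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))

    bundle["behavior_budget"].to_csv(out_dir / "behavior_budget.csv")
    for key in ("dyads", "dyads_filtered", "session_table", "session_table_filtered", "nn_scan_table"):
        if bundle.get(key) is not None and isinstance(bundle[key], pd.DataFrame):
            bundle[key].to_csv(out_dir / f"{key}.csv", index=False)
    if bundle.get("dominance") is not None:
        bundle["dominance"].to_frame().to_csv(out_dir / "dominance.csv")
    if "model_fits" in bundle:
        fits_json = {name: json.loads(fit.to_json()) for name, fit in bundle["model_fits"].items()}
        (out_dir / "model_fits.json").write_text(json.dumps(fits_json, indent=2))


def run_end_to_end_check(config: SimulationConfig | None = None, fit_glmms: bool = False) -> dict:
    """simulate -> analyze -> truth_report.  Returns the recovery summary."""
    config = config or SimulationConfig()
    dataset, interactions, truth = simulate_herd(config)
    bundle = run_analysis(dataset, interactions, fit_models=False)

    from . import models as m

    budget = bundle["behavior_budget"]
    dom = bundle["dominance"]
    foraging = pd.DataFrame(
        {
            "animal_id": budget.index,
            "foraging_prop": budget["foraging"].to_numpy(),
            "sex": [dataset.sex_of[i] for i in budget.index],
            "rank": [int(dom.ranks[i]) for i in budget.index],
        }
    )
    beta_fit = m.fit_foraging_model(foraging, compress_boundary=True)
    lmm_fit = m.fit_dyadic_lmm(bundle["dyads"], "observed")

    st = bundle["session_table"]
    nn_means = {
        t: float(st.loc[st["neighbor_type"] == t, "proportion"].mean())
        for t in st["neighbor_type"].unique()
    }
    coef_signs = {
        "rank": float(np.sign(beta_fit.estimate("rank"))),
        "same_sex": float(
            np.sign(lmm_fit.estimate("C(sex_combo, Treatment('different'))[T.same]"))
        ),
        "affiliation": float(np.sign(lmm_fit.estimate("affiliation"))),
    }
    if fit_glmms:
        glmm = m.fit_neighbor_model(st)
        coef_signs["nn1"] = float(np.sign(glmm.estimate("neighbor_typeNN1")))

    outputs = {"elo_ranks": dom.ranks, "nn_means": nn_means, "coef_signs": coef_signs}
    return truth_report(truth, outputs)
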