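"""Declarative regression contracts over the upstream model tables.

Five fits are exposed:

- beta GLM of per-individual foraging proportion on sex + dominance rank;
- binomial GLMM of session-level neighbor synchrony (successes out of valid
  scans) on neighbor type, random intercepts for hour and focal identity;
- binomial GLMM of scan-level focal/NN1 synchrony on sex combination,
  affiliation and rank difference, random intercepts for distance category,
  both identities and hour;
- Gaussian LMMs of dyadic observed synchrony and of dyadic proximity
  likelihood on the same dyadic covariates, with crossed random intercepts
  for both member identities.

The beta GLM and the Gaussian LMMs are fit with statsmodels; the binomial
GLMMs delegate to lme4 through a batched Rscript backend.  Single-term
deletion uses likelihood-ratio chi-square tests throughout (the Satterthwaite
variant for LMMs is not available in this environment); Wald statistics are
reported alongside.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ModelFit",
    "fit_foraging_model",
    "fit_neighbor_model",
    "fit_neighbor_models",
    "fit_nn_scan_model",
    "fit_nn_scan_models",
    "fit_dyadic_lmm",
]


@dataclass
class ModelFit:
    name: str
    family: str
    link: str
    params: pd.DataFrame  # columns: term, estimate, se, stat, p_wald
    drop1: dict[str, float]  # fixed term -> single-term-deletion p
    vc: dict[str, float]  # random-effect variance components
    n: int
    converged: bool
    warnings: list[str] = field(default_factory=list)
    backend: str = "statsmodels"

    def estimate(self, term: str) -> float:
        row = self.params.loc[self.params["term"] == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in model {self.name!r}")
        return float(row["estimate"].iloc[0])

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "family": self.family,
                "link": self.link,
                "params": self.params.to_dict(orient="records"),
                "drop1": self.drop1,
                "vc": self.vc,
                "n": self.n,
                "converged": self.converged,
                "warnings": self.warnings,
                "backend": self.backend,
            },
            indent=2,
        )


# --------------------------------------------------------------------------
# beta GLM: foraging proportion ~ sex + rank
# --------------------------------------------------------------------------

def fit_foraging_model(table: pd.DataFrame, compress_boundary: bool = False) -> ModelFit:
    """Beta-family GLM (logit link) of foraging proportion on sex + rank.

    ``table`` needs columns ``foraging_prop`` (strictly inside (0,1)),
    ``sex`` and ``rank``.  Proportions of exactly 0 or 1 are rejected unless
    ``compress_boundary`` applies the usual (y*(n-1)+0.5)/n shrinkage.
    """
    from statsmodels.othermod.betareg import BetaModel

    df = table.copy()
    y = df["foraging_prop"].astype(float)
    if ((y <= 0) | (y >= 1)).any():
        if not compress_boundary:
            raise ValueError(
                "foraging proportions must lie strictly in (0, 1); "
                "pass compress_boundary=True to apply (y*(n-1)+0.5)/n"
            )
        n = len(y)
        df["foraging_prop"] = (y * (n - 1) + 0.5) / n

    formula = "foraging_prop ~ C(sex) + rank"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = BetaModel.from_formula(formula, df).fit()

    drop1: dict[str, float] = {}
    for term, reduced_formula in (("sex", "foraging_prop ~ rank"), ("rank", "foraging_prop ~ C(sex)")):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            red = BetaModel.from_formula(reduced_formula, df).fit()
        lrt = 2.0 * (full.llf - red.llf)
        df_diff = len(full.params) - len(red.params)
        drop1[term] = float(sps.chi2.sf(max(lrt, 0.0), df_diff))

    params = pd.DataFrame(
        {
            "term": list(full.params.index),
            "estimate": full.params.to_numpy(),
            "se": full.bse.to_numpy(),
            "stat": full.tvalues.to_numpy(),
            "p_wald": full.pvalues.to_numpy(),
        }
    )
    return ModelFit(
        name="foraging_beta_glm",
        family="beta",
        link="logit",
        params=params,
        drop1=drop1,
        vc={},
        n=len(df),
        converged=bool(full.mle_retvals.get("converged", True)),
    )


# --------------------------------------------------------------------------
# binomial GLMMs via the lme4 backend
# --------------------------------------------------------------------------

def _run_lme4(specs: list[dict], tables: list[pd.DataFrame]) -> list[dict]:
    script = resources.files("herdsync").joinpath("lme4_fit.R")
    with tempfile.TemporaryDirectory() as tmp:
        tmpdir = Path(tmp)
        for i, tab in enumerate(tables):
            tab.to_csv(tmpdir / f"data_{i}.csv", index=False)
            specs[i]["data"] = f"data_{i}.csv"
        (tmpdir / "specs.json").write_text(json.dumps(specs))
        with resources.as_file(script) as script_path:
            proc = subprocess.run(
                ["Rscript", "--vanilla", str(script_path), str(tmpdir)],
                capture_output=True,
                text=True,
            )
        out = tmpdir / "results.json"
        if proc.returncode != 0 or not out.exists():
            raise RuntimeError(
                f"lme4 backend failed (exit {proc.returncode}):\n{proc.stderr[-2000:]}"
            )
        results = json.loads(out.read_text())
    if isinstance(results, dict):
        results = [results]
    return results


def _modelfit_from_r(name: str, res: dict) -> ModelFit:
    if not res.get("ok", False):
        raise RuntimeError(f"{name}: lme4 fit failed: {res.get('error')}")

    def _as_list(x):
        return x if isinstance(x, list) else [x]

    params = pd.DataFrame(
        {
            "term": _as_list(res["terms"]),
            "estimate": [float(v) for v in _as_list(res["estimate"])],
            "se": [float(v) for v in _as_list(res["se"])],
            "stat": [float(v) for v in _as_list(res["z"])],
            "p_wald": [float(v) for v in _as_list(res["p"])],
        }
    )
    vc = {
        str(g): float(v)
        for g, v in zip(_as_list(res.get("vc_group", [])), _as_list(res.get("vc_var", [])))
    }
    msgs = [str(m) for m in res.get("messages", []) or []]
    return ModelFit(
        name=name,
        family="binomial",
        link="logit",
        params=params,
        drop1={k: float(v) for k, v in (res.get("drop1") or {}).items()},
        vc=vc,
        n=int(res["n"]),
        converged=bool(res.get("converged", True)),
        warnings=msgs,
        backend="lme4",
    )


_NEIGHBOR_SPEC = {
    "formula": (
        "cbind(n_sync, n_valid - n_sync) ~ neighbor_type + (1 | hour) + (1 | focal_id)"
    ),
    "relevel": {"neighbor_type": "random_conspecific"},
    "factors": ["hour", "focal_id"],
}

_NN_SCAN_SPEC = {
    "formula": (
        "synchronized ~ sex_combo + affiliation + rank_diff"
        " + (1 | distance_category) + (1 | focal_id) + (1 | nn1_id) + (1 | hour)"
    ),
    "relevel": {"sex_combo": "different"},
    "factors": ["hour", "focal_id", "nn1_id", "distance_category"],
}


def fit_neighbor_models(tables: list[pd.DataFrame], drop1: bool = True) -> list[ModelFit]:
    """Batched binomial GLMMs of neighbor synchrony (one Rscript call)."""
    for t in tables:
        if t["n_sync"].nunique() == 1 and t["n_sync"].iloc[0] in (0, t["n_valid"].iloc[0]):
            warnings.warn("degenerate response: all sessions fully (un)synchronized", stacklevel=2)
    specs = [dict(_NEIGHBOR_SPEC, no_drop1=not drop1) for _ in tables]
    results = _run_lme4(specs, tables)
    return [_modelfit_from_r("neighbor_synchrony_glmm", r) for r in results]


def fit_neighbor_model(table: pd.DataFrame) -> ModelFit:
    """Binomial GLMM: synchronized scans out of valid scans ~ neighbor type,
    random intercepts for hour and focal identity; reference level is the
    random conspecific."""
    return fit_neighbor_models([table])[0]


def fit_nn_scan_models(tables: list[pd.DataFrame], drop1: bool = True) -> list[ModelFit]:
    for t in tables:
        if t["synchronized"].nunique() < 2:
            raise ValueError("scan-level response has fewer than 2 distinct values")
    specs = [dict(_NN_SCAN_SPEC, no_drop1=not drop1) for _ in tables]
    results = _run_lme4(specs, tables)
    return [_modelfit_from_r("nn_scan_glmm", r) for r in results]


def fit_nn_scan_model(table: pd.DataFrame) -> ModelFit:
    """Binomial GLMM of scan-level focal/NN1 synchrony on dyadic covariates."""
    return fit_nn_scan_models([table])[0]


# --------------------------------------------------------------------------
# Gaussian LMM with crossed member random intercepts
# --------------------------------------------------------------------------

def fit_dyadic_lmm(table: pd.DataFrame, response: str = "observed", drop1: bool = True) -> ModelFit:
    """Gaussian LMM of a symmetric dyadic response on sex_combo + affiliation
    + rank_diff with crossed random intercepts for both member identities.

    Member 1 is the lexicographically smaller id by construction of the dyad
    table; swapping all member labels leaves the fixed effects unchanged.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = table.copy()
    n_missing = int(df[response].isna().sum())
    if n_missing:
        warnings.warn(
            f"dropping {n_missing} dyads with undefined {response!r}", stacklevel=2
        )
        df = df.dropna(subset=[response])
    if df[response].nunique() < 2:
        raise ValueError(f"constant response {response!r}")
    ids = sorted(set(df["id_a"]) | set(df["id_b"]))
    df["_one"] = 1
    vc_formula = {
        "member_a": f"0 + C(id_a, levels={ids!r})",
        "member_b": f"0 + C(id_b, levels={ids!r})",
    }
    fixed = f"{response} ~ C(sex_combo, Treatment('different')) + affiliation + rank_diff"

    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = MixedLM.from_formula(fixed, groups="_one", vc_formula=vc_formula, data=df)
        res = model.fit(reml=True)
        caught.extend(str(w.message) for w in wlist)

    def _ml_fit(formula):
        model = MixedLM.from_formula(formula, groups="_one", vc_formula=vc_formula, data=df)
        for method in (None, "powell", "cg"):
            try:
                kwargs = {} if method is None else {"method": method}
                return model.fit(reml=False, **kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
        return None

    # single-term deletion by ML likelihood ratio
    drop1_p: dict[str, float] = {}
    if drop1:
        reduced = {
            "sex_combo": f"{response} ~ affiliation + rank_diff",
            "affiliation": f"{response} ~ C(sex_combo, Treatment('different')) + rank_diff",
            "rank_diff": f"{response} ~ C(sex_combo, Treatment('different')) + affiliation",
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full_ml = _ml_fit(fixed)
            for term, f_red in reduced.items():
                red = _ml_fit(f_red) if full_ml is not None else None
                if full_ml is None or red is None:
                    caught.append(f"ML refit failed for drop1 of {term!r}")
                    drop1_p[term] = float("nan")
                    continue
                lrt = 2.0 * (full_ml.llf - red.llf)
                drop1_p[term] = float(sps.chi2.sf(max(lrt, 0.0), 1))

    fe = res.fe_params
    se = res.bse_fe
    stat = fe / se
    params = pd.DataFrame(
        {
            "term": list(fe.index),
            "estimate": fe.to_numpy(),
            "se": se.to_numpy(),
            "stat": stat.to_numpy(),
            "p_wald": (2 * sps.norm.sf(np.abs(stat))).tolist(),
        }
    )
    vc = {k: float(v) for k, v in res.vcomp_to_dict().items()} if hasattr(res, "vcomp_to_dict") else {}
    if not vc:
        names = list(vc_formula)
        vc = {n: float(v) for n, v in zip(names, np.atleast_1d(res.vcomp))}
    vc["residual"] = float(res.scale)
    resid = vc["residual"]
    singular = any(
        v <= 1e-8 or v < 1e-3 * resid for k, v in vc.items() if k != "residual"
    ) or any("boundary" in w for w in caught)
    if singular:
        caught.append("singular random-effect fit (a variance component is ~0)")
    return ModelFit(
        name=f"dyadic_lmm_{response}",
        family="gaussian",
        link="identity",
        params=params,
        drop1=drop1_p,
        vc=vc,
        n=len(df),
        converged=bool(res.converged),
        warnings=caught,
    )
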