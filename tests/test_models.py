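import numpy as np
import pandas as pd
import pytest

from herdsync import models as m
from herdsync.neighbors import nn_scan_table, session_table
from herdsync.simulate import SimulationConfig, simulate_herd

SAME_SEX_TERM = "C(sex_combo, Treatment('different'))[T.same]"


def _foraging_table(rng, n=17, mu=0.6, phi=30.0, beta_rank=0.0):
    """Parametric beta draws with an optional logit-linear rank effect."""
    ranks = np.arange(1, n + 1)
    sex = rng.permutation(["female"] * 13 + ["male"] * (n - 13)) if n == 17 else rng.choice(
        ["female", "male"], size=n
    )
    eta = np.log(mu / (1 - mu)) + beta_rank * (ranks - ranks.mean())
    means = 1 / (1 + np.exp(-eta))
    y = rng.beta(means * phi, (1 - means) * phi)
    y = np.clip(y, 1e-4, 1 - 1e-4)
    return pd.DataFrame({"foraging_prop": y, "sex": sex, "rank": ranks})


def _dyad_table(rng, n_animals=10, beta_sex=0.0, sd_id=0.05, sd_res=0.05):
    ids = [f"X{i:02d}" for i in range(n_animals)]
    sexes = {i: ("female" if k < n_animals // 2 else "male") for k, i in enumerate(ids)}
    u = rng.normal(0, sd_id, n_animals)
    rows = []
    for i in range(n_animals):
        for j in range(i + 1, n_animals):
            same = sexes[ids[i]] == sexes[ids[j]]
            y = 0.5 + u[i] + u[j] + beta_sex * same + rng.normal(0, sd_res)
            rows.append(
                {
                    "id_a": ids[i],
                    "id_b": ids[j],
                    "sex_combo": "same" if same else "different",
                    "affiliation": int(rng.random() < 0.4),
                    "rank_diff": abs(i - j),
                    "observed": y,
                }
            )
    return pd.DataFrame(rows)


class TestForagingBetaGlm:
    def test_boundary_value_errors(self):
        df = pd.DataFrame(
            {"foraging_prop": [0.5, 1.0, 0.3], "sex": ["female"] * 3, "rank": [1, 2, 3]}
        )
        with pytest.raises(ValueError, match="compress_boundary"):
            m.fit_foraging_model(df)

    def test_boundary_compression_opt_in(self):
        df = pd.DataFrame(
            {
                "foraging_prop": [0.5, 1.0, 0.3, 0.6, 0.2, 0.7],
                "sex": ["female", "male"] * 3,
                "rank": [1, 2, 3, 4, 5, 6],
            }
        )
        fit = m.fit_foraging_model(df, compress_boundary=True)
        assert fit.family == "beta" and fit.link == "logit"

    def test_term_contract(self):
        rng = np.random.default_rng(0)
        fit = m.fit_foraging_model(_foraging_table(rng))
        terms = set(fit.params["term"])
        assert terms == {"Intercept", "C(sex)[T.male]", "rank", "precision"}
        assert set(fit.drop1) == {"sex", "rank"}

    def test_sign_recovery(self):
        """beta_rank > 0 gives a positive rank coefficient in >=95 of 100
        parametric replicates."""
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            fit = m.fit_foraging_model(_foraging_table(rng, beta_rank=0.06))
            hits += fit.estimate("rank") > 0
        assert hits >= 95

    def test_type_one_error(self):
        """null rank effect: drop1 LRT rejects at ~5% over 500 replicates."""
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(500):
            fit = m.fit_foraging_model(_foraging_table(rng, beta_rank=0.0))
            rejections += fit.drop1["rank"] < 0.05
        assert 0.02 <= rejections / 500 <= 0.09


class TestNeighborGlmm:
    def test_term_contract(self, sim_small):
        ds, _, _ = sim_small
        tab = session_table(ds, np.random.default_rng(0))
        fit = m.fit_neighbor_model(tab)
        assert list(fit.params["term"]) == [
            "(Intercept)",
            "neighbor_typeNN1",
            "neighbor_typeNN2",
            "neighbor_typeNN3",
        ]
        assert set(fit.drop1) == {"neighbor_type"}
        assert set(fit.vc) == {"focal_id", "hour"}
        assert fit.backend == "lme4"

    def test_ordering_recovery(self):
        """Proximity-only coupling: NN1 > NN2 > NN3 > 0 coefficients in >=90
        of 100 simulated replicates (persistent spatial clusters)."""
        tables = []
        for seed in range(100):
            cfg = SimulationConfig(
                seed=seed,
                n_sessions=150,
                copy_prob=0.7,
                prox_decay=3.0,
                arena_size=100.0,
                step_noise_sd=2.0,
                cohesion=0.01,
                attendance=0.9,
            )
            ds, _, _ = simulate_herd(cfg)
            tables.append(session_table(ds, np.random.default_rng(seed)))
        fits = m.fit_neighbor_models(tables, drop1=False)
        hits = 0
        for fit in fits:
            est = {r.term: r.estimate for r in fit.params.itertuples()}
            c1, c2, c3 = (
                est["neighbor_typeNN1"],
                est["neighbor_typeNN2"],
                est["neighbor_typeNN3"],
            )
            hits += c1 > c2 > c3 > 0
        assert hits >= 90

    def test_null_calibration(self):
        """no coupling: per-contrast Wald rejection ~5% over 150 parametric
        replicates; all three contrasts cover 0 in most replicates."""
        rng = np.random.default_rng(3)
        tables = []
        for _ in range(150):
            rows = []
            for s in range(60):
                focal = f"F{rng.integers(0, 17):02d}"
                for t in ("NN1", "NN2", "NN3", "random_conspecific"):
                    rows.append(
                        {
                            "session_id": f"S{s}",
                            "focal_id": focal,
                            "hour": 9 + s % 9,
                            "neighbor_type": t,
                            "n_sync": int(rng.binomial(4, 0.6)),
                            "n_valid": 4,
                        }
                    )
            tables.append(pd.DataFrame(rows))
        fits = m.fit_neighbor_models(tables, drop1=False)
        rejected = []
        all_cover = 0
        for fit in fits:
            p = fit.params.loc[fit.params["term"] != "(Intercept)", "p_wald"]
            rejected.extend(p < 0.05)
            all_cover += (p >= 0.05).all()
        rate = np.mean(rejected)
        assert 0.02 <= rate <= 0.09
        assert all_cover / len(fits) >= 0.85

    def test_degenerate_response_warns(self):
        rows = [
            {
                "session_id": f"S{s}",
                "focal_id": "F01",
                "hour": 9,
                "neighbor_type": t,
                "n_sync": 4,
                "n_valid": 4,
            }
            for s in range(4)
            for t in ("NN1", "random_conspecific")
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            try:
                m.fit_neighbor_model(pd.DataFrame(rows))
            except RuntimeError:
                pass  # lme4 may fail outright on the degenerate fit


class TestNNScanGlmm:
    @pytest.fixture(scope="class")
    def fits(self):
        """One strongly sex-coupled and one null simulation, batched."""
        tables = []
        for w_sex, seed in ((8.0, 21), (0.0, 22)):
            cfg = SimulationConfig(
                seed=seed, n_sessions=128, copy_prob=0.6, w_sex=w_sex, prox_decay=4.0
            )
            ds, inter, truth = simulate_herd(cfg)
            aff = truth.affiliation
            tab, _ = nn_scan_table(ds, aff, truth.ranks)
            tables.append(tab)
        return m.fit_nn_scan_models(tables)

    def test_term_contract(self, fits):
        fit = fits[0]
        assert list(fit.params["term"]) == [
            "(Intercept)",
            "sex_combosame",
            "affiliation",
            "rank_diff",
        ]
        assert set(fit.vc) == {"distance_category", "focal_id", "nn1_id", "hour"}
        assert set(fit.drop1) == {"sex_combo", "affiliation", "rank_diff"}

    def test_same_sex_coupling_sign(self, fits):
        assert fits[0].estimate("sex_combosame") > 0

    def test_null_estimates_near_zero(self, fits):
        fit = fits[1]
        assert abs(fit.estimate("sex_combosame")) < 0.8
        assert abs(fit.estimate("rank_diff")) < 0.1
        assert all(p > 0.01 for p in fit.drop1.values())

    def test_constant_response_errors(self):
        tab = pd.DataFrame(
            {
                "synchronized": [1, 1, 1],
                "sex_combo": ["same", "different", "same"],
                "affiliation": [0, 1, 0],
                "rank_diff": [1, 2, 3],
                "distance_category": ["within_1BL"] * 3,
                "focal_id": ["A", "B", "C"],
                "nn1_id": ["B", "C", "A"],
                "hour": [9, 10, 11],
            }
        )
        with pytest.raises(ValueError, match="distinct"):
            m.fit_nn_scan_model(tab)


class TestDyadicLmm:
    def test_term_contract(self):
        rng = np.random.default_rng(4)
        fit = m.fit_dyadic_lmm(_dyad_table(rng))
        assert list(fit.params["term"]) == [
            "Intercept",
            SAME_SEX_TERM,
            "affiliation",
            "rank_diff",
        ]
        assert set(fit.drop1) == {"sex_combo", "affiliation", "rank_diff"}
        assert set(fit.vc) == {"member_a", "member_b", "residual"}

    def test_member_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        table = _dyad_table(rng, beta_sex=0.05)
        fit_a = m.fit_dyadic_lmm(table)
        swapped = table.rename(columns={"id_a": "id_b", "id_b": "id_a"})
        fit_b = m.fit_dyadic_lmm(swapped)
        np.testing.assert_allclose(
            fit_a.params["estimate"], fit_b.params["estimate"], atol=1e-6
        )

    def test_constant_response_errors(self):
        rng = np.random.default_rng(6)
        table = _dyad_table(rng)
        table["observed"] = 0.5
        with pytest.raises(ValueError, match="constant"):
            m.fit_dyadic_lmm(table)

    def test_sign_recovery_direct(self):
        rng = np.random.default_rng(7)
        fit = m.fit_dyadic_lmm(_dyad_table(rng, beta_sex=0.15))
        assert fit.estimate(SAME_SEX_TERM) > 0
        assert fit.drop1["sex_combo"] < 0.01

    def test_type_one_error_wald(self):
        """null: Wald rejection of rank_diff ~5% over 500 replicates."""
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            fit = m.fit_dyadic_lmm(_dyad_table(rng), drop1=False)
            p = float(fit.params.loc[fit.params["term"] == "rank_diff", "p_wald"].iloc[0])
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_singular_fit_flagged(self):
        rng = np.random.default_rng(9)
        table = _dyad_table(rng, sd_id=0.0)  # no identity variance
        fit = m.fit_dyadic_lmm(table, drop1=False)
        assert any("singular" in w for w in fit.warnings)
        assert len(fit.params) == 4  # fixed effects still reported
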