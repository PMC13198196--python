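import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdsync.scan_data import BEHAVIOR_ORDER
from herdsync.synchrony import (
    dyad_synchrony_table,
    dyadic_observed_synchrony,
    expected_synchrony,
    fleiss_kappa,
    fleiss_kappa_from_table,
    group_synchrony_degree,
    group_synchrony_summary,
    observed_vs_expected_test,
    per_scan_degrees,
)

from conftest import make_dataset, simple_scan


def _scan_df(behaviors):
    return pd.DataFrame({"behavior": behaviors})


def brute_force_kappa(counts: np.ndarray) -> float:
    """Independent pairwise-agreement oracle for Fleiss kappa.

    P_i = (# agreeing rater pairs) / C(m, 2) per subject, chance agreement
    from pooled category shares.
    """
    counts = np.asarray(counts, dtype=float)
    m = counts.sum(axis=1)[0]
    p_is = []
    for row in counts:
        agree = sum(n * (n - 1) / 2 for n in row)
        p_is.append(agree / (m * (m - 1) / 2))
    p_bar = float(np.mean(p_is))
    shares = counts.sum(axis=0) / counts.sum()
    p_e = float((shares**2).sum())
    return (p_bar - p_e) / (1 - p_e)


class TestGroupSynchronyDegree:
    def test_mixed_scan(self):
        behaviors = ["foraging"] * 6 + ["lying", "standing"]
        assert group_synchrony_degree(_scan_df(behaviors)) == pytest.approx(75.0)

    def test_all_same(self):
        assert group_synchrony_degree(_scan_df(["lying"] * 12)) == pytest.approx(100.0)

    def test_fully_split(self):
        assert group_synchrony_degree(_scan_df(list(BEHAVIOR_ORDER))) == pytest.approx(25.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            group_synchrony_degree(_scan_df([]))

    def test_lower_bound_when_divisible_by_four(self, sim_default):
        ds = sim_default[0]
        for _, scan in ds.iter_scans():
            if len(scan) % 4 == 0:
                assert group_synchrony_degree(scan) >= 25.0


class TestGroupSynchronySummary:
    def _dataset_with_degrees(self):
        # four 20-animal scans engineered to degrees 60, 75, 95, 100
        sexes = {f"A{k:02d}": "female" for k in range(1, 21)}
        scans = []
        for i, n_major in enumerate([12, 15, 19, 20], start=1):
            behaviors = {}
            others = itertools.cycle(["lying", "standing", "walking"])
            for k in range(1, 21):
                behaviors[f"A{k:02d}"] = "foraging" if k <= n_major else next(others)
            scans.append(simple_scan(f"S{i}", 1, "A01", behaviors))
        return make_dataset(scans, sexes)

    def test_mean_and_cumulative_props(self):
        res = group_synchrony_summary(self._dataset_with_degrees())
        assert res.mean == pytest.approx(82.5)
        assert res.threshold_props == {70: 0.75, 90: 0.50, 100: 0.25}

    def test_single_full_sync_scan(self):
        sexes = {"A01": "female", "A02": "male"}
        ds = make_dataset([simple_scan("S1", 1, "A01", {"A01": "lying", "A02": "lying"})], sexes)
        res = group_synchrony_summary(ds)
        assert all(v == 1.0 for v in res.threshold_props.values())

    def test_props_non_increasing(self, sim_default):
        res = group_synchrony_summary(sim_default[0])
        values = [res.threshold_props[t] for t in sorted(res.threshold_props)]
        assert values == sorted(values, reverse=True)


class TestFleissKappa:
    def test_hand_table_exact(self):
        # 3 scans x 3 animals: (F,F,F), (F,F,L), (L,L,L)
        counts = np.array([[0, 0, 0, 3], [1, 0, 0, 2], [3, 0, 0, 0]])
        res = fleiss_kappa_from_table(counts)
        assert res.p_bar == pytest.approx(7 / 9)
        assert res.p_bar_e == pytest.approx(41 / 81)
        assert res.kappa == pytest.approx(22 / 40)

    def test_perfect_agreement(self):
        counts = np.array([[5, 0, 0, 0], [0, 5, 0, 0], [0, 0, 0, 5]])
        assert fleiss_kappa_from_table(counts).kappa == pytest.approx(1.0)

    def test_single_category_undefined(self):
        counts = np.array([[5, 0, 0, 0], [5, 0, 0, 0]])
        with pytest.raises(ValueError, match="undefined"):
            fleiss_kappa_from_table(counts)

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            counts = rng.multinomial(5, rng.dirichlet(np.ones(5)), size=5)
            expected = brute_force_kappa(counts)
            assert fleiss_kappa_from_table(counts).kappa == pytest.approx(expected, abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_kappa

        rng = np.random.default_rng(0)
        counts = rng.multinomial(17, [0.4, 0.3, 0.2, 0.1], size=12)
        assert fleiss_kappa_from_table(counts).kappa == pytest.approx(
            sm_kappa(counts), abs=1e-12
        )

    def test_uses_only_complete_scans(self):
        sexes = {"A01": "female", "A02": "male", "A03": "female"}
        scans = [
            simple_scan("S1", 1, "A01", {"A01": "lying", "A02": "lying", "A03": "lying"}),
            simple_scan("S1", 2, "A01", {"A01": "foraging", "A02": "foraging"}),  # incomplete
            simple_scan("S2", 1, "A02", {"A01": "foraging", "A02": "foraging", "A03": "foraging"}),
        ]
        res = fleiss_kappa(make_dataset(scans, sexes))
        assert res.n_subjects == 2
        assert res.n_raters == 3
        assert res.kappa == pytest.approx(1.0)

    def test_too_few_complete_scans(self):
        sexes = {"A01": "female", "A02": "male"}
        ds = make_dataset([simple_scan("S1", 1, "A01", {"A01": "lying"})], sexes)
        with pytest.raises(ValueError, match="found 0"):
            fleiss_kappa(ds)


class TestExpectedSynchrony:
    def test_uniform(self):
        p = np.full(4, 0.25)
        assert expected_synchrony(p, p) == pytest.approx(0.25)

    def test_disjoint(self):
        assert expected_synchrony([1, 0, 0, 0], [0, 1, 0, 0]) == pytest.approx(0.0)

    def test_half_half(self):
        p = [0.5, 0.5, 0, 0]
        assert expected_synchrony(p, p) == pytest.approx(0.5)

    @given(
        a=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
        b=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        a = np.array(a) / np.sum(a)
        b = np.array(b) / np.sum(b)
        e = expected_synchrony(a, b)
        assert e == pytest.approx(expected_synchrony(b, a))
        assert 0.0 <= e <= 1.0


class TestDyadicSynchrony:
    def test_three_of_four_matches(self):
        sexes = {"A01": "female", "A02": "male"}
        scans = []
        for i, (b1, b2) in enumerate(
            [("lying", "lying"), ("foraging", "foraging"), ("walking", "walking"), ("lying", "standing")],
            start=1,
        ):
            scans.append(simple_scan(f"S{i}", 1, "A01", {"A01": b1, "A02": b2}))
        res = dyadic_observed_synchrony(make_dataset(scans, sexes), ("A01", "A02"))
        assert res["n_co_present"] == 4
        assert res["observed"] == pytest.approx(0.75)

    def test_identical_streams(self):
        sexes = {"A01": "female", "A02": "male"}
        scans = [
            simple_scan(f"S{i}", 1, "A01", {"A01": b, "A02": b})
            for i, b in enumerate(["lying", "foraging", "walking"], start=1)
        ]
        res = dyadic_observed_synchrony(make_dataset(scans, sexes), ("A01", "A02"))
        assert res["observed"] == pytest.approx(1.0)

    def test_never_co_present_errors(self):
        sexes = {"A01": "female", "A02": "male"}
        scans = [
            simple_scan("S1", 1, "A01", {"A01": "lying"}),
            simple_scan("S2", 1, "A02", {"A02": "lying"}),
        ]
        with pytest.raises(ValueError, match="co-present"):
            dyadic_observed_synchrony(make_dataset(scans, sexes), ("A01", "A02"))

    def test_17_animals_gives_136_dyads(self, sim_default):
        table = dyad_synchrony_table(sim_default[0])
        assert len(table) == 136
        assert ((table["observed"] >= 0) & (table["observed"] <= 1)).all()
        assert ((table["expected"] >= 0) & (table["expected"] <= 1)).all()

    def test_permutation_null_matches_expected(self, sim_default):
        """Shuffling each animal's behavior stream across its scans breaks the
        temporal alignment but keeps every profile, so mean observed dyadic
        synchrony converges to the independence expectation."""
        ds = sim_default[0]
        sub_sessions = ds.session_ids[:40]
        small = ds.subset(ds.df["session_id"].isin(sub_sessions))
        rng = np.random.default_rng(0)
        expected_mean = dyad_synchrony_table(small)["expected"].mean()
        obs_means = []
        for _ in range(30):
            perm = small.df.copy()
            perm["behavior"] = perm.groupby("animal_id")["behavior"].transform(
                lambda s: rng.permutation(s.to_numpy())
            )
            permuted = type(small)(small.individuals, perm)
            table = dyad_synchrony_table(permuted)
            obs_means.append(table["observed"].mean())
        assert np.mean(obs_means) == pytest.approx(expected_mean, abs=0.02)


class TestObservedVsExpected:
    def test_toy_differences_give_t_five(self):
        table = pd.DataFrame(
            {
                "observed": [0.5, 0.5, 0.5, 0.6],
                "expected": [0.4, 0.4, 0.4, 0.4],
            }
        )
        res = observed_vs_expected_test(table)
        assert res["t"] == pytest.approx(5.0)
        assert res["df"] == 3

    def test_zero_variance_errors(self):
        table = pd.DataFrame({"observed": [0.5, 0.6], "expected": [0.4, 0.5]})
        with pytest.raises(ValueError, match="variance"):
            observed_vs_expected_test(table)

    def test_needs_two_dyads(self):
        table = pd.DataFrame({"observed": [0.5], "expected": [0.4]})
        with pytest.raises(ValueError):
            observed_vs_expected_test(table)
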