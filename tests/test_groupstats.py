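"""Group statistics: splits, residualization, Welch tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mibca import groupstats


def _cov(ages, ids=None):
    ids = ids or [f"s{i}" for i in range(len(ages))]
    return pd.DataFrame({"age": ages}, index=ids)


class TestSplitGroups:
    def test_age_threshold(self):
        g1, g2 = groupstats.split_groups(_cov([30, 35, 45]), "age", threshold=40)
        assert len(g1) == 2 and len(g2) == 1

    def test_categorical_label(self):
        cov = pd.DataFrame({"sex": ["M", "F", "F"]}, index=["a", "b", "c"])
        g1, g2 = groupstats.split_groups(cov, "sex", label="F")
        assert set(g1) == {"b", "c"} and g2 == ["a"]

    def test_fifteen_young_twenty_old_regime(self, rng):
        ages = np.concatenate([rng.integers(19, 38, 15), rng.integers(42, 74, 20)])
        g1, g2 = groupstats.split_groups(_cov(list(ages)), "age", threshold=40)
        assert (len(g1), len(g2)) == (15, 20)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            groupstats.split_groups(_cov([50, 60]), "age", threshold=40)


class TestRegressCovariates:
    def test_self_covariate_gives_zero_residuals(self, rng):
        y = rng.normal(size=20)
        resid = groupstats.regress_covariates(y, y[:, None])
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_orthogonal_covariate_preserves_centered_values(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        x = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal by construction
        resid = groupstats.regress_covariates(y, x)
        np.testing.assert_allclose(resid, y - y.mean(), atol=1e-12)

    def test_matches_normal_equation_solve(self, rng):
        y = rng.normal(size=30)
        X = rng.normal(size=(30, 3))
        design = np.column_stack([np.ones(30), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(
            groupstats.regress_covariates(y, X), y - design @ beta, atol=1e-10
        )

    def test_residuals_sum_to_zero(self, rng):
        resid = groupstats.regress_covariates(
            rng.normal(size=25), rng.normal(size=(25, 2))
        )
        assert resid.sum() == pytest.approx(0.0, abs=1e-10)

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="rank-deficient"):
            groupstats.regress_covariates(
                rng.normal(size=10), np.column_stack([x, 2 * x])
            )


class TestGroupwiseTest:
    def test_welch_t_matches_hand_formula(self):
        a = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        b = pd.DataFrame({"m": [4.0, 6.0, 8.0]})
        res = groupstats.groupwise_test(a, b)
        m1, m2 = 2.0, 6.0
        v1, v2 = np.var([1, 2, 3], ddof=1), np.var([4, 6, 8], ddof=1)
        t_hand = (m2 - m1) / np.sqrt(v1 / 3 + v2 / 3)
        row = res.table.iloc[0]
        assert row["t"] == pytest.approx(t_hand)
        assert row["direction"] == "increase"

    def test_swap_symmetry(self, rng):
        a = pd.DataFrame({"m": rng.normal(size=10)})
        b = pd.DataFrame({"m": rng.normal(1.0, 1, size=12)})
        fwd = groupstats.groupwise_test(a, b).table.iloc[0]
        rev = groupstats.groupwise_test(b, a).table.iloc[0]
        assert fwd["p"] == pytest.approx(rev["p"])
        assert {fwd["direction"], rev["direction"]} == {"increase", "decrease"}

    def test_null_rejection_rate_calibrated(self, rng):
        n_sim, hits = 300, 0
        for _ in range(n_sim):
            a = pd.DataFrame({"m": rng.normal(size=15)})
            b = pd.DataFrame({"m": rng.normal(size=20)})
            res = groupstats.groupwise_test(a, b, alpha=0.05)
            hits += bool(res.table["significant"].iloc[0])
        rate = hits / n_sim
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sim) + 1e-9

    def test_bonferroni_controls_family(self, rng):
        n_sim, fam = 200, 20
        fw_hits = 0
        for _ in range(n_sim):
            a = pd.DataFrame(rng.normal(size=(10, fam)),
                             columns=[f"t{i}" for i in range(fam)])
            b = pd.DataFrame(rng.normal(size=(10, fam)),
                             columns=[f"t{i}" for i in range(fam)])
            res = groupstats.groupwise_test(a, b, correction="bonferroni")
            fw_hits += bool(res.table["significant"].any())
        assert fw_hits / n_sim <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_independent_covariate_leaves_inference_close(self, rng):
        a_vals = rng.normal(size=15)
        b_vals = rng.normal(1.0, 1, size=20)
        cov_a = pd.DataFrame({"nuisance": rng.normal(size=15)})
        cov_b = pd.DataFrame({"nuisance": rng.normal(size=20)})
        plain = groupstats.groupwise_test(
            pd.DataFrame({"m": a_vals}), pd.DataFrame({"m": b_vals})
        ).table.iloc[0]
        adj = groupstats.groupwise_test(
            pd.DataFrame({"m": a_vals}), pd.DataFrame({"m": b_vals}),
            covariates_a=cov_a, covariates_b=cov_b,
        ).table.iloc[0]
        # independent covariate: direction unchanged, t close
        assert plain["direction"] == adj["direction"]
        assert adj["t"] == pytest.approx(plain["t"], rel=0.3)

    def test_zero_variance_target_skipped(self):
        a = pd.DataFrame({"m": [1.0, 1.0, 1.0]})
        b = pd.DataFrame({"m": [1.0, 1.0, 1.0]})
        res = groupstats.groupwise_test(a, b)
        assert np.isnan(res.table["p"].iloc[0])
        assert not res.table["significant"].iloc[0]

    def test_detection_rate_near_closed_form_power(self, rng):
        """Planted 1-SD shift at n=(15, 20): empirical detection vs. the
        noncentral-t power of the two-sample test."""
        n1, n2, d, alpha = 15, 20, 1.0, 0.05
        df = n1 + n2 - 2
        ncp = d / np.sqrt(1 / n1 + 1 / n2)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        power = 1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
        n_sim, hits = 400, 0
        for _ in range(n_sim):
            a = pd.DataFrame({"m": rng.normal(size=n1)})
            b = pd.DataFrame({"m": rng.normal(d, 1, size=n2)})
            hits += bool(
                groupstats.groupwise_test(a, b, alpha=alpha)
                .table["significant"].iloc[0]
            )
        assert abs(hits / n_sim - power) < 0.05


def test_edge_table_upper_triangle(rng):
    from conftest import random_binary_cm
    from mibca.types import SubjectStack

    mats = {f"s{i}": random_binary_cm(rng, n=4) for i in range(3)}
    stack = SubjectStack(subject_ids=sorted(mats), matrices=mats)
    tab = groupstats.edge_table(stack)
    assert tab.shape == (3, 6)
    assert tab.loc["s0", "1-2"] == mats["s0"].values[0, 1]
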