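import numpy as np
import pandas as pd
import pytest
from scipy import stats

from finepgs.evaluate import (
    _mann_whitney_auc,
    auc_binary,
    auc_to_liability_r2,
    r2_quantitative,
    score,
)
from finepgs.sumstats import PGSModel


def _model(weights_beta):
    n = len(weights_beta)
    df = pd.DataFrame({
        "chrom": ["1"] * n,
        "pos": np.arange(1, n + 1),
        "other_allele": ["A"] * n,
        "effect_allele": ["G"] * n,
        "beta": [b for _, b in weights_beta],
        "weight_ppi": [w for w, _ in weights_beta],
    })
    df["weight"] = df["weight_ppi"] * df["beta"]
    return PGSModel(df)


def _dosages(G, ids=None):
    n, p = G.shape
    ids = ids or [f"1:{j + 1}:A:G" for j in range(p)]
    return pd.DataFrame(G, index=[f"I{i}" for i in range(n)], columns=ids)


class TestScore:
    def test_all_zero_dosages_give_zero(self):
        m = _model([(0.5, 0.2), (0.9, -0.1)])
        s, _ = score(m, _dosages(np.zeros((4, 2))))
        assert np.all(s == 0)

    def test_single_variant_direct_product(self):
        m = _model([(1 - 1e-9, 0.5)])  # weight*beta ~ 0.5
        s, _ = score(m, _dosages(np.array([[0.0], [1.0], [2.0]])))
        np.testing.assert_allclose(s, [0.0, 0.5, 1.0], rtol=1e-8)

    def test_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        m = _model([(w, b) for w, b in zip(rng.uniform(0, 1, 20), rng.normal(0, 0.2, 20))])
        G = rng.integers(0, 3, size=(10, 20)).astype(float)
        s, _ = score(m, _dosages(G))
        w = m.table["weight"].to_numpy()
        expected = [sum(w[i] * G[j, i] for i in range(20)) for j in range(10)]
        np.testing.assert_allclose(s, expected)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        m = _model([(w, b) for w, b in zip(rng.uniform(0, 1, 5), rng.normal(size=5))])
        G1 = rng.integers(0, 3, (6, 5)).astype(float)
        G2 = rng.integers(0, 3, (6, 5)).astype(float)
        a, b = 0.25, 0.5  # keeps aG1+bG2 within dosage bounds
        s, _ = score(m, _dosages(a * G1 + b * G2))
        s1, _ = score(m, _dosages(G1))
        s2, _ = score(m, _dosages(G2))
        np.testing.assert_allclose(s, a * s1 + b * s2)

    def test_swapped_orientation_uses_two_minus_g(self):
        m = _model([(0.5, 0.4)])
        G = np.array([[0.0], [2.0]])
        s_fwd, _ = score(m, _dosages(G))
        # dosage file keyed with ref/alt swapped: counts the model's other allele
        s_rev, _ = score(m, _dosages(G, ids=["1:1:G:A"]))
        np.testing.assert_allclose(s_rev.to_numpy(), s_fwd.to_numpy()[::-1])

    def test_missing_model_variants_counted(self):
        m = _model([(0.5, 0.4), (0.5, 0.1)])
        s, n_missing = score(m, _dosages(np.ones((3, 1)), ids=["1:1:A:G"]))
        assert n_missing == 1

    def test_empty_intersection_hard_error(self):
        m = _model([(0.5, 0.4)])
        with pytest.raises(ValueError, match="no overlap"):
            score(m, _dosages(np.ones((3, 1)), ids=["9:9:A:G"]))

    def test_missing_dosages_mean_imputed(self):
        m = _model([(0.5, 0.4)])
        G = np.array([[0.0], [2.0], [np.nan]])
        s, _ = score(m, _dosages(G))
        w = m.table["weight"].iloc[0]
        np.testing.assert_allclose(s, [0.0, 2 * w, 1.0 * w])  # imputed with column mean 1.0


class TestAUC:
    def test_independent_score_near_half(self):
        rng = np.random.default_rng(2)
        status = rng.integers(0, 2, 4000)
        res = auc_binary(status, None, rng.normal(size=4000), n_boot=50, seed=0)
        assert abs(res.estimate - 0.5) < 0.03
        assert res.K == pytest.approx(status.mean())

    def test_perfect_separation(self):
        status = np.array([0] * 50 + [1] * 50)
        s = np.concatenate([np.zeros(50), np.ones(50)])
        assert _mann_whitney_auc(s, status) == 1.0

    def test_pairwise_counting_oracle(self):
        rng = np.random.default_rng(3)
        status = rng.integers(0, 2, 200)
        x = rng.normal(size=200)
        cases, ctrls = x[status == 1], x[status == 0]
        wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in ctrls)
        expected = wins / (len(cases) * len(ctrls))
        assert _mann_whitney_auc(x, status) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        status = rng.integers(0, 2, 500)
        x = rng.normal(size=500) + status
        assert _mann_whitney_auc(x, status) == pytest.approx(roc_auc_score(status, x), abs=1e-12)

    def test_single_class_hard_error(self):
        with pytest.raises(ValueError, match="cases and controls"):
            auc_binary(np.ones(10), None, np.arange(10.0), n_boot=10)

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(5)
        status = rng.integers(0, 2, 300)
        x = rng.normal(size=300) + 0.5 * status
        r1 = auc_binary(status, None, x, n_boot=200, seed=42)
        r2 = auc_binary(status, None, x, n_boot=200, seed=42)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_covariate_adjustment_removes_confounding(self):
        rng = np.random.default_rng(6)
        n = 3000
        confounder = rng.normal(size=n)
        status = (confounder + rng.normal(size=n) > 1).astype(int)
        s = confounder + 0.05 * rng.normal(size=n)  # score is pure confounder
        raw = auc_binary(status, None, s, n_boot=10, seed=0)
        adj = auc_binary(status, pd.DataFrame({"pc1": confounder}), s, n_boot=10, seed=0)
        assert raw.estimate > 0.7
        assert abs(adj.estimate - 0.5) < 0.05


class TestLiabilityConversion:
    def test_auc_half_maps_to_exactly_zero(self):
        for K in (0.01, 0.1, 0.3):
            assert auc_to_liability_r2(0.5, K) == 0.0

    def test_strictly_increasing_in_auc(self):
        aucs = np.linspace(0.5, 0.99, 50)
        r2s = [auc_to_liability_r2(a, 0.1) for a in aucs]
        assert np.all(np.diff(r2s) > 0)

    def test_anti_predictive_auc_hard_error(self):
        with pytest.raises(ValueError, match="orientation"):
            auc_to_liability_r2(0.4, 0.1)

    @pytest.mark.parametrize("K", [0.01, 0.05, 0.2])
    def test_forward_simulation_round_trip(self, K):
        rng = np.random.default_rng(7)
        n, r2_true = 200_000, 0.15
        s = rng.normal(size=n) * np.sqrt(r2_true)
        liab = s + rng.normal(size=n) * np.sqrt(1 - r2_true)
        case = (liab > np.quantile(liab, 1 - K)).astype(int)
        auc = _mann_whitney_auc(s, case)
        assert abs(auc_to_liability_r2(auc, K) - r2_true) < 0.02


class TestR2Quantitative:
    def test_independent_score_near_zero(self):
        rng = np.random.default_rng(8)
        res = r2_quantitative(rng.normal(size=2000), None, rng.normal(size=2000), n_boot=20)
        assert res.estimate < 0.01

    def test_perfect_predictor(self):
        rng = np.random.default_rng(9)
        n = 500
        cov = pd.DataFrame({"age": rng.normal(size=n)})
        trait = 2.0 * cov["age"].to_numpy() + rng.normal(size=n)
        from finepgs.evaluate import _residualize

        resid = _residualize(trait, cov)  # score equal to the trait residual itself
        res = r2_quantitative(trait, cov, resid, n_boot=20)
        assert res.estimate == pytest.approx(1.0, abs=1e-10)

    def test_no_covariates_equals_plain_squared_correlation(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=400)
        s = 0.3 * y + rng.normal(size=400)
        res = r2_quantitative(y, None, s, n_boot=20)
        assert res.estimate == pytest.approx(np.corrcoef(y, s)[0, 1] ** 2, rel=1e-10)

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=100)
        cov = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="b"):
            r2_quantitative(rng.normal(size=100), cov, rng.normal(size=100), n_boot=5)

    def test_incomplete_rows_dropped(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=100)
        y[:5] = np.nan
        res = r2_quantitative(y, None, rng.normal(size=100), n_boot=10)
        assert res.n_individuals == 95
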