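import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from feralpop import offset, simdata
from feralpop.offset import (
    env_pca,
    environmental_distance,
    estimate_gea_coefficients,
    genetic_offset,
    go_surface,
)


@pytest.fixture(scope="module")
def random_covariates():
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.normal(size=(10, 19)),
        index=[f"P{i}" for i in range(10)],
        columns=[f"bio{k}" for k in range(1, 20)],
    )


class TestEnvPca:
    def test_projection_identity(self, random_covariates):
        design = env_pca(random_covariates, n_keep=7)
        proj = design.project(random_covariates.to_numpy())
        np.testing.assert_allclose(proj, design.scores, atol=1e-10)

    def test_rank_one_first_pc_explains_all(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(8, 1))
        v = rng.normal(size=(1, 19))
        design = env_pca(u @ v, n_keep=3)
        assert design.variance_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_explained_matches_eigen_oracle(self, random_covariates):
        x = random_covariates.to_numpy()
        xs = (x - x.mean(0)) / x.std(0)
        evals = np.linalg.eigvalsh(xs.T @ xs)[::-1]
        design = env_pca(random_covariates, n_keep=5)
        np.testing.assert_allclose(
            design.variance_explained, (evals / evals.sum())[:5], atol=1e-10
        )

    def test_variance_threshold_mode(self, random_covariates):
        design = env_pca(random_covariates, variance_threshold=0.9)
        cum = np.cumsum(design.variance_explained)
        assert cum[-1] >= 0.9
        assert design.n_pcs == np.searchsorted(cum, 0.9) + 1

    def test_constant_column_dropped(self, random_covariates):
        cov = random_covariates.copy()
        cov["bio1"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            design = env_pca(cov, n_keep=3)
        assert "bio1" not in design.covariate_names


class TestGeaCoefficients:
    def test_noiseless_single_pc_exact(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(12, 1))
        es = (scores - scores.mean(0)) / scores.std(0)
        b_true = np.array([[0.1], [-0.2], [0.05]])
        freqs = 0.5 + b_true @ es.T
        b_hat = estimate_gea_coefficients(freqs, scores)
        np.testing.assert_allclose(b_hat, b_true, atol=1e-10)

    def test_null_centered_on_zero(self):
        rng = np.random.default_rng(3)
        freqs = rng.uniform(0.2, 0.8, size=(500, 12))
        b_hat = estimate_gea_coefficients(freqs, rng.normal(size=(12, 3)))
        assert abs(b_hat.mean()) < 0.01

    def test_too_few_populations_rejected(self):
        with pytest.raises(ValueError):
            estimate_gea_coefficients(np.zeros((5, 4)), np.zeros((4, 3)))

    def test_collinear_scores_force_ridge(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=(10, 1))
        scores = np.column_stack([s, s])  # perfectly collinear
        freqs = rng.uniform(0.3, 0.7, size=(20, 10))
        with pytest.warns(UserWarning, match="ridge"):
            b = estimate_gea_coefficients(freqs, scores)
        assert np.isfinite(b).all()

    def test_recovery_on_simulated_truth(self):
        design, truth, _ = simdata.generate_environment(
            32, 5, effect_scale=0.3, seed=5, n_snps=3000
        )
        b_hat = estimate_gea_coefficients(truth.pop_freqs, design.scores)
        aff = truth.affected
        corr = np.corrcoef(b_hat[aff].ravel(), truth.b_true[aff].ravel())[0, 1]
        assert corr > 0.8


class TestGeneticOffset:
    def test_zero_distance(self):
        b = np.ones((5, 3))
        e = np.array([1.0, 2.0, 3.0])
        assert genetic_offset(b, e, e) == 0.0

    def test_identity_metric_reduction(self):
        # B'B = n_snp * I -> GO = ||d||^2
        n_snp, n_pc = 4, 2
        b = np.zeros((n_snp, n_pc))
        b[:2, 0] = np.sqrt(n_snp / 2)
        b[2:, 1] = np.sqrt(n_snp / 2)
        d = np.array([0.3, -0.4])
        e_ref = np.zeros(2)
        assert genetic_offset(b, d, e_ref) == pytest.approx(d @ d)

    def test_two_by_two_toy(self):
        b = np.array([[1.0, 0.0], [0.0, 2.0]])
        go = genetic_offset(b, np.array([1.0, 1.0]), np.zeros(2))
        assert go == pytest.approx((1 + 4) / 2)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            genetic_offset(np.ones((3, 2)), np.ones(3), np.zeros(3))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        b = rng.normal(size=(6, 3))
        go = genetic_offset(b, rng.normal(size=3), rng.normal(size=3))
        assert go >= 0

    def test_proportional_to_delta_when_btb_identity(self):
        rng = np.random.default_rng(6)
        q, _ = np.linalg.qr(rng.normal(size=(8, 3)))
        b = q * np.sqrt(8)  # B'B = 8 I
        for _ in range(5):
            e1, e2 = rng.normal(size=3), rng.normal(size=3)
            go = genetic_offset(b, e1, e2)
            delta = environmental_distance(e1, e2)
            assert go == pytest.approx(3 * delta**2)


class TestEnvironmentalDistance:
    @pytest.mark.parametrize(
        "e1, e2, ne, expected",
        [
            ([1.0, 2.0], [1.0, 2.0], None, 0.0),
            ([3.0], [0.0], 1, 3.0),
            ([1.0] * 7, [0.0] * 7, 7, 1.0),
        ],
    )
    def test_values(self, e1, e2, ne, expected):
        assert environmental_distance(
            np.array(e1), np.array(e2), ne
        ) == pytest.approx(expected)


class TestGoSurface:
    def test_pointwise_equivalence(self):
        design, truth, cov = simdata.generate_environment(
            16, 3, effect_scale=0.2, seed=7, n_snps=500
        )
        b = estimate_gea_coefficients(truth.pop_freqs, design.scores)
        e_ref = design.scores[0]
        grid = cov.iloc[:4].copy()
        grid.insert(0, "lat", np.arange(4.0))
        grid.insert(0, "lon", np.arange(4.0))
        surf = go_surface(grid, design, b, e_ref)
        for k in range(4):
            direct = genetic_offset(b, design.scores[k], e_ref)
            assert surf["go"].iloc[k] == pytest.approx(direct)
        # reference location's own covariates -> GO = 0
        assert surf["go"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_missing_covariate_rows_skipped(self):
        design, truth, cov = simdata.generate_environment(
            16, 3, effect_scale=0.2, seed=8, n_snps=200
        )
        b = estimate_gea_coefficients(truth.pop_freqs, design.scores)
        grid = cov.iloc[:3].copy()
        grid.insert(0, "lat", np.zeros(3))
        grid.insert(0, "lon", np.zeros(3))
        grid.iloc[1, 5] = np.nan
        surf = go_surface(grid, design, b, design.scores[0])
        assert len(surf) == 2
        assert surf.attrs["skipped"] == 1


class TestEnvironmentGenerator:
    def test_null_effect_scale(self):
        design, truth, _ = simdata.generate_environment(
            20, 3, effect_scale=0.0, seed=9, n_snps=400
        )
        assert np.all(truth.b_true == 0)
        b_hat = estimate_gea_coefficients(truth.pop_freqs, design.scores)
        assert abs(b_hat.mean()) < 0.01

    def test_negative_effect_scale_rejected(self):
        with pytest.raises(ValueError):
            simdata.generate_environment(10, 2, effect_scale=-1.0, seed=1)

    def test_sign_agreement_with_strong_effect(self):
        design, truth, _ = simdata.generate_environment(
            32, 1, effect_scale=0.5, seed=10, n_snps=2000
        )
        aff = truth.affected
        f = truth.pop_freqs[aff]
        s = truth.scores_std[:, 0]
        slope = ((f - f.mean(axis=1, keepdims=True)) * s).sum(axis=1)
        agree = np.sign(slope) == np.sign(truth.b_true[aff, 0])
        assert agree.mean() > 0.95

    def test_identical_environments_zero_go(self):
        design, truth, _ = simdata.generate_environment(
            16, 3, effect_scale=0.4, seed=11, n_snps=300
        )
        b = estimate_gea_coefficients(truth.pop_freqs, design.scores)
        e = design.scores[3]
        assert genetic_offset(b, e, e.copy()) == 0.0

    def test_go_rank_correlation_with_truth(self):
        from scipy.stats import spearmanr

        design, truth, _ = simdata.generate_environment(
            32, 5, effect_scale=0.3, seed=12, n_snps=3000
        )
        b_hat = estimate_gea_coefficients(truth.pop_freqs, design.scores)
        rng = np.random.default_rng(13)
        queries = rng.normal(size=(20, 5))
        e_ref = design.scores[0]
        go_hat = [genetic_offset(b_hat, q, e_ref) for q in queries]
        # truth operates on standardized scores; map queries consistently
        go_true = [genetic_offset(truth.b_true, q, e_ref) for q in queries]
        rho = spearmanr(go_hat, go_true).statistic
        assert rho > 0.9
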