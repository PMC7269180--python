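import numpy as np
import pandas as pd
import pytest

from atacdecon.deconv import clip_to_proportions, estimate_proportions, proportions_frame, simpls_fit
from atacdecon.profiles import MixtureMatrix
from atacdecon.signature import SignatureMatrix, condition_number, zscore_columns
from atacdecon.transform import TransformSpec


def make_signature(values: np.ndarray, types=None) -> SignatureMatrix:
    types = types or [f"type{j + 1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"f{i + 1}" for i in range(values.shape[0])], columns=types)
    return SignatureMatrix(
        values=df, condition_number=condition_number(zscore_columns(df)), n_per_type=0
    )


class TestSimplsFit:
    def test_univariate_equals_ols_slope(self, rng):
        x = rng.normal(size=(25, 1))
        y = 3.0 * x[:, 0] + rng.normal(size=25)
        coef = simpls_fit(x, y, 1)[0, 0]
        xc, yc = x[:, 0] - x[:, 0].mean(), y - y.mean()
        assert coef == pytest.approx(np.dot(xc, yc) / np.dot(xc, xc))

    def test_full_components_match_normal_equations(self, rng):
        worst = 0.0
        for _ in range(50):
            n, p, q = int(rng.integers(8, 40)), int(rng.integers(2, 7)), int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            Y = rng.normal(size=(n, q))
            C = simpls_fit(X, Y, p)
            Xc, Yc = X - X.mean(0), Y - Y.mean(0)
            C_ols = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
            worst = max(worst, float(np.abs(C - C_ols).max()))
        assert worst < 1e-8

    def test_noiseless_coefficient_recovery(self, rng):
        X = rng.normal(size=(30, 4))
        C_true = rng.normal(size=(4, 2))
        Y = X @ C_true
        C = simpls_fit(X, Y, 4)
        np.testing.assert_allclose(C, C_true, atol=1e-8)

    def test_single_response_matches_nipals_pls1(self, rng):
        # for one response variable SIMPLS and NIPALS PLS1 coincide at every
        # component count: independent cross-check against scikit-learn
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        for ncomp in (1, 3, 6):
            ours = simpls_fit(X, y, ncomp)[:, 0]
            ref = sklearn.PLSRegression(n_components=ncomp, scale=False).fit(X, y[:, None])
            np.testing.assert_allclose(ours, ref.coef_.ravel(), atol=1e-10)

    def test_zero_variance_column_is_an_error(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            simpls_fit(X, rng.normal(size=10), 2)

    def test_component_overrun_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="n_components"):
            simpls_fit(X, rng.normal(size=5), 5)


class TestClipToProportions:
    def test_worked_example(self):
        fractions, degenerate = clip_to_proportions(np.array([0.5, -0.2, 0.7]))
        np.testing.assert_allclose(fractions, [5 / 12, 0.0, 7 / 12])
        assert not degenerate

    def test_all_nonpositive_flags_degenerate(self):
        fractions, degenerate = clip_to_proportions(np.array([-0.5, -0.1, 0.0]))
        assert degenerate
        np.testing.assert_array_equal(fractions, [0.0, 0.0, 0.0])

    def test_sum_to_one_within_tolerance(self, rng):
        for _ in range(20):
            f, deg = clip_to_proportions(rng.normal(size=6))
            if not deg:
                assert abs(f.sum() - 1) < 1e-9
                assert (f >= 0).all()


class TestEstimateProportions:
    def test_exact_noiseless_recovery(self, rng):
        B = rng.lognormal(3, 1, size=(300, 5))
        sig = make_signature(B)
        f = rng.dirichlet(np.ones(5))
        mix = MixtureMatrix(values=pd.DataFrame({"m1": B @ f}, index=sig.feature_ids))
        (est,) = estimate_proportions(sig, mix, transform=TransformSpec(mode="none"))
        np.testing.assert_allclose(est.fractions, f, atol=1e-6)
        assert est.n_components == 5

    def test_permutation_equivariance(self, rng):
        B = rng.lognormal(3, 1, size=(60, 4))
        f = rng.dirichlet(np.ones(4))
        mix = MixtureMatrix(
            values=pd.DataFrame({"m1": B @ f}, index=[f"f{i + 1}" for i in range(60)])
        )
        perm = [2, 0, 3, 1]
        sig = make_signature(B, types=["A", "B", "C", "D"])
        sig_p = make_signature(B[:, perm], types=["C", "A", "D", "B"])
        (e1,) = estimate_proportions(sig, mix, transform=TransformSpec(mode="none"))
        (e2,) = estimate_proportions(sig_p, mix, transform=TransformSpec(mode="none"))
        s1 = e1.as_series().sort_index()
        s2 = e2.as_series().sort_index()
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)

    def test_noisy_mixtures_recovered(self, planted_dataset, rng):
        # 100 mixtures, 5 types, 10% multiplicative noise: per-mixture
        # correlation between truth and estimate stays high on average
        truth = planted_dataset
        B = truth.type_means
        sig = SignatureMatrix(
            values=B, condition_number=condition_number(zscore_columns(B)), n_per_type=0
        )
        estimates = estimate_proportions(sig, truth.mixtures, transform=TransformSpec(mode="none"))
        rs = [
            np.corrcoef(e.fractions, truth.fractions.loc[e.mixture_id, e.cell_types])[0, 1]
            for e in estimates
        ]
        assert np.mean(rs) >= 0.95

    def test_rmse_degrades_monotonically_with_noise(self):
        from atacdecon.evaluate import rmse
        from atacdecon.simulate import SimulationConfig, simulate_dataset

        mean_rmse = []
        for cv in (0.0, 0.05, 0.1, 0.2):
            truth = simulate_dataset(SimulationConfig(noise_cv=cv, n_mixtures=40, seed=99))
            sig = SignatureMatrix(
                values=truth.type_means,
                condition_number=condition_number(zscore_columns(truth.type_means)),
                n_per_type=0,
            )
            ests = estimate_proportions(sig, truth.mixtures, transform=TransformSpec(mode="none"))
            mean_rmse.append(
                np.mean([rmse(e.fractions, truth.fractions.loc[e.mixture_id]) for e in ests])
            )
        assert mean_rmse == sorted(mean_rmse)
        assert mean_rmse[0] < 1e-9  # noise-free is exact

    def test_empty_feature_intersection_mentions_id_format(self, rng):
        B = rng.lognormal(3, 1, size=(20, 3))
        sig = make_signature(B)
        mix = MixtureMatrix(
            values=pd.DataFrame({"m1": np.ones(20)}, index=[f"other{i}" for i in range(20)])
        )
        with pytest.raises(ValueError, match="feature ids"):
            estimate_proportions(sig, mix)

    def test_proportions_frame_layout(self, rng):
        B = rng.lognormal(3, 1, size=(40, 3))
        sig = make_signature(B)
        F = rng.dirichlet(np.ones(3), size=4)
        mix = MixtureMatrix(
            values=pd.DataFrame(B @ F.T, index=sig.feature_ids, columns=[f"m{j}" for j in range(4)])
        )
        ests = estimate_proportions(sig, mix, transform=TransformSpec(mode="none"))
        frame = proportions_frame(ests)
        assert frame.shape == (4, 3)
        np.testing.assert_allclose(frame.sum(axis=1), 1.0, atol=1e-9)
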