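"""From-scratch LDA: scatter decomposition, prediction, stratified splits."""

import numpy as np
import pandas as pd
import pytest

import volsense as vs
from volsense.lda import (
    SingularScatterError,
    evaluate_split,
    load_results,
    stratified_split,
)
from volsense.lda import test_set_size as held_out_size
from volsense.signal import ValidationError


def two_gaussians(n=200, p=5, seed=0, delta=0.8):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(p, p))
    cov = A @ A.T / p + np.eye(p)
    X = np.vstack([
        rng.multivariate_normal(np.zeros(p), cov, n),
        rng.multivariate_normal(np.full(p, delta), cov, n),
    ])
    y = ["a"] * n + ["b"] * n
    return X, y


class TestFit:
    def test_at_most_k_minus_1_directions(self, gaussian_4class):
        X, y = gaussian_4class
        res = vs.LinearDiscriminantModel(X, y).fit()
        assert res.n_components == 3
        assert res.basis.shape == (X.shape[1], 3)

    def test_fisher_closed_form_direction(self):
        """Two classes: first direction ∝ S_w⁻¹(μ₁ − μ₂)."""
        X, y = two_gaussians()
        res = vs.LinearDiscriminantModel(X, y).fit(shrinkage=0.0)
        w = res.basis[:, 0]
        w_ref = np.linalg.solve(res.pooled_within_scatter,
                                res.class_means[0] - res.class_means[1])
        cos = abs(w @ w_ref) / (np.linalg.norm(w) * np.linalg.norm(w_ref))
        assert cos >= 0.999

    def test_equal_class_means_give_null_eigenvalues(self):
        rng = np.random.default_rng(1)
        block = rng.normal(size=(40, 4))
        X = np.vstack([block, block])  # identical class clouds
        y = ["a"] * 40 + ["b"] * 40
        res = vs.LinearDiscriminantModel(X, y).fit(shrinkage=0.0)
        assert np.all(np.abs(res.eigenvalues) <= 1e-8)

    def test_eigenvalues_nonnegative_and_sorted(self, gaussian_4class):
        X, y = gaussian_4class
        res = vs.LinearDiscriminantModel(X, y).fit()
        assert np.all(res.eigenvalues >= -1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-10)

    def test_priors_from_training_frequencies(self):
        X, y = two_gaussians(n=100)
        X, y = np.vstack([X, X[:50]]), y + ["a"] * 50
        res = vs.LinearDiscriminantModel(X, y).fit()
        assert res.priors[0] == pytest.approx(150 / 250)
        assert res.priors.sum() == pytest.approx(1.0)

    def test_singular_scatter_without_shrinkage_raises(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(20, 2))
        X = np.hstack([base, base])  # perfectly collinear features
        y = ["a"] * 10 + ["b"] * 10
        with pytest.raises((SingularScatterError, np.linalg.LinAlgError)):
            res = vs.LinearDiscriminantModel(X, y).fit(shrinkage=0.0)
            # generalized eigh may not raise on all platforms; then the
            # basis must be unusable (non-finite)
            if np.all(np.isfinite(res.basis)):
                raise SingularScatterError("expected singular scatter")

    def test_small_class_rejected(self):
        with pytest.raises(ValidationError):
            vs.LinearDiscriminantModel(np.zeros((3, 2)), ["a", "a", "b"])

    def test_nonfinite_rejected(self):
        X = np.zeros((8, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            vs.LinearDiscriminantModel(X, ["a"] * 4 + ["b"] * 4)

    def test_from_dataframe_roundtrip(self, gaussian_4class):
        X, y = gaussian_4class
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        df["class"] = y
        res = vs.LinearDiscriminantModel.from_dataframe(df).fit()
        assert res.feature_names == [f"f{i}" for i in range(X.shape[1])]


class TestProjectPredict:
    def test_projected_class_means_match(self, gaussian_4class):
        X, y = gaussian_4class
        res = vs.LinearDiscriminantModel(X, y).fit()
        np.testing.assert_allclose(res.project(res.class_means), res.z_means)

    def test_projection_linearity_under_shift(self, gaussian_4class):
        X, y = gaussian_4class
        res = vs.LinearDiscriminantModel(X, y).fit()
        shift = np.full(X.shape[1], 2.5)
        np.testing.assert_allclose(res.project(X + shift),
                                   res.project(X) + shift @ res.basis)

    def test_posteriors_sum_to_one(self, gaussian_4class):
        X, y = gaussian_4class
        res = vs.LinearDiscriminantModel(X, y).fit()
        _, post = res.predict(X)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_class_mean_point_predicted_as_class(self):
        X, y = two_gaussians(delta=6.0)
        res = vs.LinearDiscriminantModel(X, y).fit()
        pred, _ = res.predict(res.class_means)
        assert list(pred) == ["a", "b"]

    def test_separable_data_perfect_training_accuracy(self):
        X, y = two_gaussians(delta=10.0)
        res = vs.LinearDiscriminantModel(X, y).fit()
        assert res.training_accuracy == 1.0

    def test_dimension_mismatch_rejected(self, gaussian_4class):
        X, y = gaussian_4class
        res = vs.LinearDiscriminantModel(X, y).fit()
        with pytest.raises(ValidationError):
            res.project(X[:, :3])

    def test_deterministic_refit(self, gaussian_4class):
        X, y = gaussian_4class
        r1 = vs.LinearDiscriminantModel(X, y).fit()
        r2 = vs.LinearDiscriminantModel(X, y).fit()
        np.testing.assert_array_equal(r1.basis, r2.basis)

    def test_sklearn_label_agreement(self, gaussian_4class):
        """Independent reference implementation agrees on ≥99% of labels."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = gaussian_4class
        mine, _ = vs.LinearDiscriminantModel(X, y).fit(shrinkage=0.0).predict(X)
        ref = LinearDiscriminantAnalysis().fit(X, y).predict(X)
        assert np.mean(mine == ref) >= 0.99

    def test_summary_mentions_key_quantities(self, gaussian_4class):
        X, y = gaussian_4class
        s = vs.LinearDiscriminantModel(X, y).fit().summary()
        assert "Shrinkage" in s and "Eigenvalues" in s and "c0" in s

    def test_save_load_roundtrip(self, tmp_path, gaussian_4class):
        X, y = gaussian_4class
        res = vs.LinearDiscriminantModel(X, y).fit()
        res.save(tmp_path / "model.json")
        loaded = load_results(tmp_path / "model.json")
        pred_a, _ = res.predict(X[:50])
        pred_b, _ = loaded.predict(X[:50])
        np.testing.assert_array_equal(pred_a, pred_b)


class TestSplits:
    @pytest.mark.parametrize("n,expected", [(228, 46), (209, 42)])
    def test_ceiling_twenty_percent(self, n, expected):
        assert held_out_size(n, 0.2) == expected

    def test_stratified_counts(self):
        y = np.repeat(["a", "b", "c", "d"], 10)
        train, test = stratified_split(y, 0.2, seed=0)
        assert len(test) == 8  # 2 per class
        for c in "abcd":
            assert (y[test] == c).sum() == 2
        assert sorted(np.r_[train, test].tolist()) == list(range(40))

    def test_tiny_class_infeasible(self):
        with pytest.raises(ValidationError):
            stratified_split(["a", "a", "b"], 0.2, seed=0)

    def test_evaluate_split_chance_level_with_permuted_labels(self):
        """Shuffled labels give accuracy inside the binomial 99% CI of 1/k."""
        from scipy.stats import binom

        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 6))
        y = rng.permutation(np.repeat(["a", "b", "c", "d"], 100))
        ev = evaluate_split(X, y, test_fraction=0.2, seed=1)
        n = len(ev.test_index)
        lo = binom.ppf(0.005, n, 0.25) / n
        hi = binom.ppf(0.995, n, 0.25) / n
        assert lo <= ev.accuracy <= hi

    def test_evaluate_split_on_separated_data(self):
        X, y = two_gaussians(delta=10.0)
        ev = evaluate_split(X, y, seed=0)
        assert ev.accuracy == 1.0
        assert len(ev.test_index) == 80  # ceil(0.2 * 200) per class
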