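"""Classifier oracles: normal equations, stepwise partial-F, SAE gradients."""

import numpy as np
import pytest
from scipy import stats as sps

from p300cble.classifiers import (
    LinearModel,
    fit_ls,
    fit_sae,
    fit_swlda,
    kl_sparsity,
    sae_cost_grad,
)
from p300cble.preprocess import FeatureMatrix, Standardizer


def make_fm(X, y):
    X = np.asarray(X, dtype=float)
    n = len(X)
    return FeatureMatrix(
        X=X,
        y=np.asarray(y, dtype=float),
        feature_layout=[("ch00", i) for i in range(X.shape[1])],
        stim_code=np.ones(n, dtype=int),
        char_index=np.zeros(n, dtype=int),
        sequence_index=np.arange(n),
    )


def separable_fm(n=60, d=6, seed=0):
    """Linearly separable toy set: feature 0 carries the class, rest noise."""
    rng = np.random.default_rng(seed)
    y = np.where(np.arange(n) % 6 == 0, 1.0, -1.0)
    X = rng.standard_normal((n, d)) * 0.1
    X[:, 0] += 3.0 * y
    return make_fm(X, y)


class TestLeastSquares:
    def test_antisymmetric_pair(self):
        m = fit_ls(make_fm([[1.0], [-1.0]], [1.0, -1.0]))
        assert m.weights[0] == pytest.approx(1.0)
        assert m.bias == pytest.approx(0.0)

    def test_normal_equations_residual_orthogonality(self):
        rng = np.random.default_rng(2)
        fm = make_fm(rng.standard_normal((50, 8)), rng.choice([-1.0, 1.0], 50))
        m = fit_ls(fm)
        Xs = m.standardizer.transform(fm.X)
        Xa = np.column_stack([Xs, np.ones(50)])
        coef = np.concatenate([m.weights, [m.bias]])
        assert np.max(np.abs(Xa.T @ (Xa @ coef - fm.y))) < 1e-8

    def test_duplicating_rows_leaves_model_unchanged(self):
        rng = np.random.default_rng(3)
        fm = make_fm(rng.standard_normal((30, 4)), rng.choice([-1.0, 1.0], 30))
        m1 = fit_ls(fm)
        fm2 = make_fm(np.vstack([fm.X, fm.X]), np.concatenate([fm.y, fm.y]))
        m2 = fit_ls(fm2)
        assert np.allclose(m1.weights, m2.weights)
        assert m1.bias == pytest.approx(m2.bias)


class TestSwlda:
    def test_planted_feature_selected_noise_rejected(self):
        """Feature 0 equals the label; feature 1 is independent noise."""
        rng = np.random.default_rng(4)
        y = np.repeat([1.0, -1.0], 20)
        X = np.column_stack([y + 0.01 * rng.standard_normal(40), rng.standard_normal(40)])
        m = fit_swlda(make_fm(X, y))
        assert list(m.selected_features) == [0]

    def test_selection_agrees_with_hand_partial_f(self):
        """Hand-computed partial-F p-values predict exactly which features
        clear the entry threshold: the informative column is far below it,
        the noise columns far above."""
        rng = np.random.default_rng(5)
        n = 40
        y = np.repeat([1.0, -1.0], 20)
        X = rng.standard_normal((n, 3))
        X[:, 2] += 2.0 * y  # strongly informative
        fm = make_fm(X, y)

        def p_first_step(col):
            # classical partial F of adding one column to the intercept model
            xs = Standardizer.fit(X).transform(X)[:, col]
            X1 = np.column_stack([np.ones(n), xs])
            b = np.linalg.lstsq(X1, y, rcond=None)[0]
            rss1 = np.sum((y - X1 @ b) ** 2)
            rss0 = np.sum((y - y.mean()) ** 2)
            F = (rss0 - rss1) / (rss1 / (n - 2))
            return sps.f.sf(F, 1, n - 2)

        p_hand = [p_first_step(c) for c in range(3)]
        assert p_hand[2] < 0.05 < min(p_hand[0], p_hand[1])
        m = fit_swlda(fm)
        assert list(m.selected_features) == [2]

    def test_max_features_cap(self):
        rng = np.random.default_rng(6)
        n, d = 200, 500
        y = rng.choice([-1.0, 1.0], n)
        X = 0.5 * rng.standard_normal((n, d)) + y[:, None]  # all informative
        m = fit_swlda(make_fm(X, y))
        assert len(m.selected_features) <= 60

    def test_degenerates_to_full_ls(self):
        rng = np.random.default_rng(7)
        fm = make_fm(rng.standard_normal((50, 8)), rng.choice([-1.0, 1.0], 50))
        m_sw = fit_swlda(fm, p_enter=1.0, p_remove=1.0, max_features=8)
        m_ls = fit_ls(fm)
        assert np.allclose(m_sw.weights, m_ls.weights, atol=1e-10)
        assert m_sw.bias == pytest.approx(m_ls.bias)

    def test_empty_model_raises(self):
        rng = np.random.default_rng(8)
        fm = make_fm(rng.standard_normal((30, 5)), rng.choice([-1.0, 1.0], 30))
        with pytest.raises(RuntimeError, match="empty model"):
            fit_swlda(fm, p_enter=1e-12)

    def test_selection_invariant_to_column_permutation(self):
        rng = np.random.default_rng(9)
        y = np.repeat([1.0, -1.0], 25)
        X = rng.standard_normal((50, 10))
        X[:, 3] += 1.5 * y
        X[:, 7] += 1.0 * y
        sel = set(fit_swlda(make_fm(X, y)).selected_features)
        perm = rng.permutation(10)
        sel_p = set(fit_swlda(make_fm(X[:, perm], y)).selected_features)
        assert {int(perm[i]) for i in sel_p} == sel

    def test_unselected_feature_does_not_affect_score(self):
        fm = separable_fm()
        m = fit_swlda(fm)
        unsel = [i for i in range(fm.X.shape[1]) if i not in set(m.selected_features)]
        assert unsel, "toy set should leave some features unselected"
        X2 = fm.X.copy()
        X2[:, unsel[0]] += 100.0
        assert np.array_equal(m.score(fm.X), m.score(X2))


class TestSae:
    def test_kl_zero_at_target_activation(self):
        assert kl_sparsity(0.05, np.full(7, 0.05)) == 0.0
        assert kl_sparsity(0.3, np.array([0.3, 0.3])) == 0.0

    def test_kl_positive_otherwise(self):
        assert kl_sparsity(0.05, np.array([0.2])) > 0

    def test_analytic_gradient_matches_central_differences(self):
        """6-input, 4-hidden toy network; relative error <= 1e-5."""
        rng = np.random.default_rng(10)
        d, hidden, n = 6, 4, 9
        X = rng.random((n, d))
        n_par = hidden * d + hidden + d * hidden + d
        theta = rng.uniform(-0.5, 0.5, n_par)
        cost, grad = sae_cost_grad(theta, X, hidden, lam=0.01, beta=2.0, rho=0.1)
        eps = 1e-6
        num = np.empty(n_par)
        for i in range(n_par):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            cp, _ = sae_cost_grad(tp, X, hidden, lam=0.01, beta=2.0, rho=0.1)
            cm, _ = sae_cost_grad(tm, X, hidden, lam=0.01, beta=2.0, rho=0.1)
            num[i] = (cp - cm) / (2 * eps)
        rel = np.linalg.norm(grad - num) / np.linalg.norm(grad + num)
        assert rel <= 1e-5

    def test_autoencoder_capacity_without_regularization(self):
        """beta=0, lam=0, hidden=D: low-rank structured data reconstructed
        to within 1% of its variance."""
        rng = np.random.default_rng(11)
        basis = rng.standard_normal((2, 8))
        X = rng.standard_normal((10, 2)) @ basis  # rank-2 structure
        fm = make_fm(X, np.where(np.arange(10) % 2 == 0, 1.0, -1.0))
        m = fit_sae(fm, hidden=8, lam=0.0, beta=0.0, max_iter=4000, seed=0)
        x01, xhat = m.reconstruct(fm.X)
        assert np.mean((x01 - xhat) ** 2) <= 0.01 * np.var(x01)

    def test_scores_are_probabilities(self):
        fm = separable_fm()
        m = fit_sae(fm, hidden=5, max_iter=150, seed=0)
        s = m.score(fm.X)
        assert np.all((s > 0) & (s < 1))

    def test_training_trace_non_increasing(self):
        fm = separable_fm(n=80, d=10, seed=12)
        m = fit_sae(fm, hidden=6, max_iter=200, seed=1)
        trace = np.asarray(m.training_trace)
        assert len(trace) > 5
        # non-increasing within line-search tolerance
        assert np.all(np.diff(trace) <= 1e-8 * np.abs(trace[:-1]) + 1e-12)

    def test_nonfinite_cost_aborts(self):
        X = np.array([[1e300, -1e300]] * 4)
        theta = np.full(2 * 2 + 2 + 2 * 2 + 2, 1e150)
        with pytest.raises(FloatingPointError):
            sae_cost_grad(theta, X, 2, 0.0, 0.0, 0.05)


class TestScoreContract:
    def test_ls_direct_formula(self):
        m = LinearModel(
            weights=np.array([1.0]),
            bias=0.0,
            standardizer=Standardizer(mean=np.zeros(1), scale=np.ones(1)),
        )
        assert m.score(np.array([[0.5]]))[0] == pytest.approx(0.5)

    def test_feature_dimension_mismatch_raises(self):
        fm = separable_fm()
        m = fit_ls(fm)
        with pytest.raises(ValueError):
            m.score(np.ones((3, fm.X.shape[1] + 1)))

    @pytest.mark.parametrize("fit", [fit_ls, fit_swlda,
                                     # toy-sized regularization: with few input
                                     # dims the full-scale sparsity penalty
                                     # collapses the encoder
                                     lambda fm: fit_sae(fm, hidden=6, lam=1e-3, beta=1.0,
                                                        rho=0.2, max_iter=500, seed=0)])
    def test_all_classifiers_separate_separable_data(self, fit):
        """Shared conformance: one real score per trial, perfectly ranking a
        linearly separable toy set."""
        fm = separable_fm(n=120, d=5, seed=13)
        m = fit(fm)
        s = m.score(fm.X)
        assert s.shape == (120,)
        assert s[fm.y > 0].min() > s[fm.y < 0].max()

    def test_scoring_deterministic(self):
        fm = separable_fm()
        m = fit_sae(fm, hidden=5, max_iter=100, seed=0)
        assert np.array_equal(m.score(fm.X), m.score(fm.X))
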