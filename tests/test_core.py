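"""Surprisal decomposition: SVD estimate, reconstruction, error bars,
sample-group separation."""

import numpy as np
import pandas as pd
import pytest

import surprisalx as sx
from surprisalx.core import decompose, lambda_error_bounds, log_transform, reconstruct

from conftest import make_matrix


def toy_Y(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestLogTransform:
    @pytest.mark.parametrize(
        "x, floor, expected",
        [(np.e, 1e-6, 1.0), (1.0, 1e-6, 0.0), (0.0, 0.01, np.log(0.01))],
    )
    def test_values(self, x, floor, expected):
        m = make_matrix([[x, x]])
        Y = log_transform(m, floor=floor)
        assert Y.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_floor(self):
        with pytest.raises(ValueError):
            log_transform(make_matrix([[1.0, 1.0]]), floor=0.0)


class TestDecompose:
    def test_rank_one_input(self):
        col = np.array([1.0, 2.0, 3.0])
        Y = toy_Y(np.column_stack([col, col, col]))
        model = decompose(Y)
        assert model.singular_values[1:] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(model.lam[1:], 0.0, atol=1e-12)

    def test_full_reconstruction_exact(self):
        rng = np.random.default_rng(0)
        Y = toy_Y(rng.normal(loc=3.0, size=(40, 6)))
        model = decompose(Y)
        full = reconstruct(model, model.n_components - 1)
        np.testing.assert_allclose(full.to_numpy(), Y.to_numpy(), atol=1e-8)

    def test_exp_reconstruction_equals_floored_matrix(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.uniform(0.0, 20.0, size=(30, 5)))
        Y = log_transform(m, floor=0.01)
        model = decompose(Y)
        X_hat = np.exp(reconstruct(model, model.n_components - 1).to_numpy())
        np.testing.assert_allclose(X_hat, np.maximum(m.values, 0.01), rtol=1e-8)

    def test_toy_matches_eigendecomposition_oracle(self):
        # independent route: eigendecompose Y^T Y for singular values and
        # sample-side factors
        Y = toy_Y([[1, 1], [2, 0], [0, 2]])
        model = decompose(Y)
        evals, evecs = np.linalg.eigh(Y.to_numpy().T @ Y.to_numpy())
        order = np.argsort(evals)[::-1]
        np.testing.assert_allclose(
            model.singular_values, np.sqrt(evals[order]), atol=1e-10
        )
        for a in range(2):
            expected = np.sqrt(evals[order][a]) * evecs[:, order[a]]
            got = model.lam[a]
            assert min(
                np.abs(got - expected).max(), np.abs(got + expected).max()
            ) < 1e-10

    def test_balanced_state_positive_and_deterministic(self):
        rng = np.random.default_rng(2)
        Y = toy_Y(rng.uniform(1.0, 4.0, size=(20, 6)))
        m1, m2 = decompose(Y), decompose(Y)
        assert (m1.lam[0] > 0).all()
        np.testing.assert_array_equal(m1.G, m2.G)
        np.testing.assert_array_equal(m1.lam, m2.lam)

    def test_orthonormal_weights_and_sorted_spectrum(self):
        rng = np.random.default_rng(3)
        Y = toy_Y(rng.normal(loc=3.0, size=(15, 7)))
        model = decompose(Y)
        gram = model.G.T @ model.G
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-8)
        assert (np.diff(model.singular_values) <= 1e-12).all()

    def test_mixed_sign_lambda0_is_error(self):
        Y = toy_Y([[1.0, -1.0]])
        with pytest.raises(ValueError, match="balanced-state"):
            decompose(Y)

    def test_reference_group_orientation(self):
        rng = np.random.default_rng(4)
        Y = toy_Y(rng.uniform(1, 3, size=(10, 4)), samples=list("abcd"))
        for ref in (["a", "b"], ["c", "d"]):
            model = decompose(Y, reference={1: ref})
            assert model.lambdas(1)[sorted(ref)[0]] > 0

    def test_eckart_young_truncation_error(self):
        rng = np.random.default_rng(5)
        for shape in [(4, 3), (8, 6), (6, 5)]:
            Y = toy_Y(rng.normal(loc=3.0, size=shape))
            model = decompose(Y)
            for k in range(model.n_components):
                err = np.linalg.norm(
                    Y.to_numpy() - reconstruct(model, k).to_numpy(), "fro"
                )
                expected = np.sqrt((model.singular_values[k + 1 :] ** 2).sum())
                assert err == pytest.approx(expected, abs=1e-8)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            decompose(toy_Y([[1.0], [2.0]]))


class TestErrorBounds:
    def _model(self, n_genes=50, n_samples=4, seed=6):
        rng = np.random.default_rng(seed)
        Y = toy_Y(rng.uniform(1, 4, size=(n_genes, n_samples)))
        return decompose(Y), Y

    def test_zero_dispersion_gives_zero_bars(self):
        model, Y = self._model()
        sigma = pd.DataFrame(0.0, index=Y.index, columns=Y.columns)
        for method in ("norm_bound", "propagated_sd"):
            b = lambda_error_bounds(model, sigma, method=method)
            assert (b.values.to_numpy() == 0).all()

    def test_propagated_sd_with_constant_sigma_is_sigma(self):
        # unit-norm weight columns turn a constant per-gene sd c into a
        # propagated sd of exactly c for every component and sample
        model, Y = self._model()
        c = 0.37
        sigma = pd.DataFrame(c, index=Y.index, columns=Y.columns)
        b = lambda_error_bounds(model, sigma, method="propagated_sd")
        np.testing.assert_allclose(b.values.to_numpy(), c, rtol=1e-10)

    def test_norm_bound_dominates_propagated_sd(self):
        model, Y = self._model()
        rng = np.random.default_rng(7)
        sigma = pd.DataFrame(
            rng.uniform(0, 0.3, size=Y.shape), index=Y.index, columns=Y.columns
        )
        hi = lambda_error_bounds(model, sigma, method="norm_bound").values
        lo = lambda_error_bounds(model, sigma, method="propagated_sd").values
        assert (hi.to_numpy() >= lo.to_numpy() - 1e-12).all()

    def test_monotone_in_dispersion(self):
        model, Y = self._model()
        rng = np.random.default_rng(8)
        sigma = pd.DataFrame(
            rng.uniform(0, 0.3, size=Y.shape), index=Y.index, columns=Y.columns
        )
        bigger = sigma.copy()
        bigger.iloc[3, 1] += 0.5
        for method in ("norm_bound", "propagated_sd"):
            b1 = lambda_error_bounds(model, sigma, method=method).values.to_numpy()
            b2 = lambda_error_bounds(model, bigger, method=method).values.to_numpy()
            assert (b2 >= b1 - 1e-12).all()

    def test_negative_dispersion_rejected(self):
        model, Y = self._model()
        sigma = pd.DataFrame(-0.1, index=Y.index, columns=Y.columns)
        with pytest.raises(ValueError):
            lambda_error_bounds(model, sigma)

    def test_bootstrap_errors_scale_with_noise(self, grid_design):
        rng = np.random.default_rng(9)
        base = rng.uniform(1, 3, size=(30, 1))
        sds = {}
        for noise in (0.05, 0.5):
            X = np.exp(np.log(base) + rng.normal(0, noise, size=(30, 8)))
            m = make_matrix(X, samples=grid_design.sample_ids)
            sd = sx.bootstrap_lambda_errors(
                m, grid_design, n_boot=50, n_constraints=1, seed=1
            )
            sds[noise] = sd.loc["lambda0"].mean()
        assert sds[0.5] > sds[0.05]


class TestGroupSeparation:
    def _model_with_lambda(self, lam1, samples):
        model, _ = TestErrorBounds()._model(n_samples=len(samples))
        model.sample_ids = list(samples)
        model.lam = model.lam.copy()
        model.lam[1] = np.asarray(lam1, dtype=float)
        return model

    def test_perfect_separation(self):
        model = self._model_with_lambda([1, 2, -1, -2], list("abcd"))
        rep = sx.group_separation(model, 1, (["a", "b"], ["c", "d"]))
        assert rep.separating and rep.agreement == 1.0
        assert rep.majority_sign_a == -rep.majority_sign_b

    def test_uniform_sign_is_not_separating(self):
        model = self._model_with_lambda([1, 2, 3, 4], list("abcd"))
        rep = sx.group_separation(model, 1, (["a", "b"], ["c", "d"]))
        assert not rep.separating

    def test_zero_lambda_flagged(self):
        model = self._model_with_lambda([1, 0, -1, -2], list("abcd"))
        rep = sx.group_separation(model, 1, (["a", "b"], ["c", "d"]))
        assert rep.zero_samples == ["b"] and not rep.separating

    def test_grouping_must_cover_samples(self):
        model = self._model_with_lambda([1, 2, -1, -2], list("abcd"))
        with pytest.raises(ValueError):
            sx.group_separation(model, 1, (["a"], ["c", "d"]))


class TestLambdaZeroStability:
    def test_balanced_state_nearly_constant_on_synthetic_data(self, default_model):
        # the planted constraints carry at most ~20% of the baseline
        # energy, so lambda_0 must vary by less than that across samples
        lam0 = default_model.lambdas(0)
        rel_range = (lam0.max() - lam0.min()) / lam0.mean()
        assert rel_range < 0.20
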