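"""Standardization, eigendecomposition, retention, Varimax and scoring."""

import numpy as np
import pandas as pd
import pytest

from grassid import pca
from grassid.errors import DegenerateColumn, NoComponents, SingularInput
from grassid.reference import REFERENCE_SCORE_COEFFICIENTS


def varimax_grid_oracle(loadings, n_angles=1441, max_rounds=60):
    """Best varimax criterion reachable by exhaustive planar-angle search."""
    L = np.array(loadings, float)
    k = L.shape[1]
    angles = np.linspace(0.0, np.pi / 2.0, n_angles, endpoint=False)
    best = pca.varimax_criterion(L)
    for _ in range(max_rounds):
        improved = False
        for i in range(k - 1):
            for j in range(i + 1, k):
                pair = L[:, [i, j]]
                for phi in angles:
                    g = np.array(
                        [[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]]
                    )
                    cand = L.copy()
                    cand[:, [i, j]] = pair @ g
                    crit = pca.varimax_criterion(cand)
                    if crit > best + 1e-12:
                        best, L = crit, cand
                        pair = L[:, [i, j]]
                        improved = True
        if not improved:
            break
    return best


class TestStandardize:
    def test_simple_column(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z, means, sds = pca.standardize(table, ["a"])
        assert np.allclose(z[:, 0], [-1, 0, 1])
        assert means[0] == 2.0 and sds[0] == 1.0

    def test_already_standardized_unchanged(self, rng):
        x = rng.normal(size=500)
        x = (x - x.mean()) / x.std(ddof=1)
        z, _, _ = pca.standardize(pd.DataFrame({"a": x}), ["a"])
        assert np.allclose(z[:, 0], x, atol=1e-12)

    def test_round_trip_recovers_input(self, rng):
        table = pd.DataFrame(rng.normal(2, 5, size=(50, 3)), columns=list("abc"))
        z, means, sds = pca.standardize(table, list("abc"))
        assert np.allclose(z * sds + means, table.to_numpy(), atol=1e-12)

    def test_degenerate_column_raises(self):
        with pytest.raises(DegenerateColumn):
            pca.standardize(pd.DataFrame({"a": [1.0, 1.0, 1.0]}), ["a"])


class TestFitPca:
    def test_perfectly_correlated_pair_gives_eigenvalues_two_zero(self, rng):
        x = rng.normal(size=100)
        z, *_ = pca.standardize(pd.DataFrame({"a": x, "b": 2 * x + 1}), ["a", "b"])
        eigvals, loadings = pca.fit_pca(z)
        assert np.allclose(eigvals, [2.0, 0.0], atol=1e-10)

    def test_independent_variables_have_unit_eigenvalues(self, rng):
        z, *_ = pca.standardize(
            pd.DataFrame(rng.normal(size=(5000, 4)), columns=list("abcd")), list("abcd")
        )
        eigvals, _ = pca.fit_pca(z)
        assert np.allclose(eigvals, 1.0, atol=0.15)

    def test_eigenvalues_sum_to_feature_count(self, rng):
        z, *_ = pca.standardize(
            pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde")), list("abcde")
        )
        eigvals, loadings = pca.fit_pca(z)
        assert eigvals.sum() == pytest.approx(5.0, abs=1e-8)
        assert np.all(np.diff(eigvals) <= 1e-12)
        # loading column dominant entries are positive
        dom = np.abs(loadings).argmax(axis=0)
        assert (loadings[dom, np.arange(5)] >= 0).all()

    def test_too_few_rows_raise(self, rng):
        with pytest.raises(SingularInput):
            pca.fit_pca(rng.normal(size=(3, 5)))


class TestRetention:
    def test_borderline_third_eigenvalue_is_included(self):
        assert pca.retain_components(np.array([2.50, 1.51, 1.00, 0.4, 0.3, 0.29])) == 3

    def test_zero_tolerance_keeps_all_at_one(self):
        assert pca.retain_components(np.array([3.0, 1.0, 1.0, 1.0]), kaiser_tolerance=0.0) == 4

    def test_nothing_retained_raises(self):
        with pytest.raises(NoComponents):
            pca.retain_components(np.array([0.9, 0.1]))


class TestVarimax:
    def test_single_component_is_untouched(self, rng):
        L = rng.normal(size=(6, 1))
        rotated, rotation = pca.varimax(L)
        sign = np.sign(L[np.abs(L[:, 0]).argmax(), 0])
        assert np.allclose(rotated[:, 0], sign * L[:, 0])
        assert rotation.shape == (1, 1)

    def test_perfect_simple_structure_is_a_fixed_point(self):
        L = np.array([[0.9, 0.0], [0.8, 0.0], [0.0, 0.7], [0.0, 0.6]])
        rotated, rotation = pca.varimax(L, row_normalize=False)
        assert np.allclose(np.abs(rotated), np.abs(L), atol=1e-8)
        assert np.allclose(rotation.T @ rotation, np.eye(2), atol=1e-10)

    def test_rotation_is_orthogonal_and_preserves_communalities(self, rng):
        L = rng.normal(size=(6, 3))
        rotated, rotation = pca.varimax(L)
        assert np.allclose(rotation.T @ rotation, np.eye(3), atol=1e-8)
        assert np.allclose((rotated**2).sum(1), (L**2).sum(1), atol=1e-8)
        assert np.allclose(rotated, L @ rotation, atol=1e-8)

    def test_criterion_never_decreases_and_matches_grid_search(self, rng):
        for _ in range(3):
            L = rng.normal(size=(6, 3))
            before = pca.varimax_criterion(L)
            rotated, _ = pca.varimax(L, row_normalize=False)
            after = pca.varimax_criterion(rotated)
            assert after >= before - 1e-12
            assert after == pytest.approx(varimax_grid_oracle(L), abs=1e-4)


class TestScoring:
    def test_identity_correlation_returns_the_loadings(self, rng):
        L = rng.normal(size=(4, 2))
        assert np.allclose(pca.score_coefficients(np.eye(4), L), L)

    def test_fitted_scores_are_standardized_and_uncorrelated(self, rng):
        latent = rng.normal(size=(400, 3))
        noise = rng.normal(size=(400, 6))
        x = latent @ rng.normal(size=(3, 6)) + 0.6 * noise
        table = pd.DataFrame(x, columns=list("abcdef"))
        model = pca.fit_model(table, list("abcdef"), kaiser_tolerance=0.5)
        scores = model.score(table)
        assert np.allclose(scores.mean(), 0.0, atol=1e-10)
        assert np.allclose(scores.var(ddof=1), 1.0, atol=1e-6)
        c = np.corrcoef(scores.to_numpy().T)
        assert np.allclose(c - np.diag(np.diag(c)), 0.0, atol=1e-6)

    def test_row_at_the_feature_means_scores_zero(self, rng):
        table = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        model = pca.fit_model(table, list("abc"), kaiser_tolerance=1.0)
        row = pd.DataFrame([table[list("abc")].mean().to_dict()])
        assert np.allclose(model.score(row).to_numpy(), 0.0, atol=1e-10)

    def test_reference_coefficients_score_a_standardized_unit_row(self):
        z = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        scores = pca.score_standardized(REFERENCE_SCORE_COEFFICIENTS, z)
        assert np.allclose(scores[0], [0.482, 0.127, -0.081])

    def test_explained_pct_sums_to_100(self, small_feature_table):
        from grassid.selection import correlation_matrix, select_features

        kept = select_features(correlation_matrix(small_feature_table)).kept
        model = pca.fit_model(small_feature_table, kept)
        assert model.explained_pct.sum() == pytest.approx(100.0, abs=1e-8)
        assert np.allclose(
            model.explained_pct, model.eigenvalues / len(kept) * 100.0, atol=1e-12
        )

    def test_model_round_trips_through_json(self, tmp_path, rng):
        table = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        model = pca.fit_model(table, list("abcd"), kaiser_tolerance=0.6)
        model.to_json(tmp_path / "m.json")
        back = pca.PcaModel.from_json(tmp_path / "m.json")
        assert np.allclose(back.score(table), model.score(table))


def test_three_factor_loading_pattern_is_recovered():
    """Rotated loadings recover a known {0, 0.8} simple structure at n = 500."""
    rng = np.random.default_rng(42)
    pattern = np.zeros((6, 3))
    for j in range(3):
        pattern[2 * j : 2 * j + 2, j] = 0.8
    factors = rng.normal(size=(500, 3))
    unique_sd = np.sqrt(1.0 - 0.64)
    x = factors @ pattern.T + unique_sd * rng.normal(size=(500, 6))
    table = pd.DataFrame(x, columns=list("abcdef"))
    model = pca.fit_model(table, list("abcdef"), kaiser_tolerance=0.5)
    assert model.retained_k == 3
    fitted = model.rotated_loadings
    # align fitted columns to generating columns by absolute inner product
    used = set()
    max_dev = 0.0
    for j in range(3):
        dots = [abs(fitted[:, c] @ pattern[:, j]) for c in range(3)]
        c = int(np.argmax(dots))
        assert c not in used
        used.add(c)
        sign = np.sign(fitted[:, c] @ pattern[:, j])
        max_dev = max(max_dev, np.abs(sign * fitted[:, c] - pattern[:, j]).max())
    assert max_dev <= 0.15
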