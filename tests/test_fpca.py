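"""Functional PCA: eigenstructure, scores, reconstruction, simulation."""

import numpy as np
import pandas as pd
import pytest

from mbresil import (
    FPCAError,
    Trajectory,
    TrajectorySet,
    fpca_fit,
    fpca_scores,
    reconstruct,
    score_distance_correlation,
    score_group_summary,
    simulate_family,
)
from mbresil.fpca import quadrature_weights
from mbresil.synthetic import generate_fpca_family

GRID = np.array([0.0, 0.5, 3.0, 6.0, 24.0, 48.0])


def family_from_matrix(X, grid=GRID):
    trs = [Trajectory(f"s{i}", "c", grid, X[i]) for i in range(X.shape[0])]
    return TrajectorySet(trs, grid=np.asarray(grid, dtype=float))


def random_family(rng, n=12, grid=GRID):
    return family_from_matrix(rng.uniform(0.0, 10.0, size=(n, len(grid))), grid)


def unit_phi(grid, w):
    phi = np.sin(np.linspace(0.3, 2.4, len(grid)))
    return phi / np.sqrt(w @ phi**2)


class TestQuadratureWeights:
    def test_trapezoid_on_uneven_grid(self):
        w = quadrature_weights(GRID)
        d = np.diff(GRID)
        np.testing.assert_allclose(w[0], d[0] / 2)
        np.testing.assert_allclose(w[-1], d[-1] / 2)
        np.testing.assert_allclose(w.sum(), GRID[-1] - GRID[0])

    def test_short_grid_falls_back_to_uniform(self):
        np.testing.assert_allclose(quadrature_weights(np.array([0.0, 5.0])), [1, 1])


class TestFpcaFit:
    def test_identical_curves_zero_spectrum(self):
        X = np.tile(np.array([0.0, 1.0, 4.0, 3.0, 2.0, 1.0]), (4, 1))
        model = fpca_fit(family_from_matrix(X), K=2)
        np.testing.assert_allclose(model.eigenvalues, 0.0, atol=1e-20)
        np.testing.assert_allclose(model.mean_curve, X[0])

    def test_two_curve_family_against_eigh_oracle(self):
        w = quadrature_weights(GRID)
        phi = unit_phi(GRID, w)
        mu = np.full(len(GRID), 5.0)
        ts = family_from_matrix(np.vstack([mu + phi, mu - phi]))
        model = fpca_fit(ts, K=1)
        # brute-force oracle: eigendecompose W^1/2 C W^1/2 directly
        C = 2 * np.outer(phi, phi)  # (n-1)=1 denominator over the two deviations
        sw = np.sqrt(w)
        oracle = np.linalg.eigvalsh(sw[:, None] * C * sw[None, :]).max()
        assert model.eigenvalues[0] == pytest.approx(oracle, abs=1e-10)
        assert model.explained_fractions[0] == pytest.approx(1.0, abs=1e-10)
        scores = fpca_scores(model, ts)["FPCA1"].to_numpy()
        np.testing.assert_allclose(np.sort(scores), [-1.0, 1.0], atol=1e-10)

    def test_orthonormality_and_ordering(self, rng):
        model = fpca_fit(random_family(rng, n=15), K=5)
        gram = (model.eigenfunctions * model.weights) @ model.eigenfunctions.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert model.explained_fractions.sum() <= 1 + 1e-10

    def test_trace_preservation(self, rng):
        ts = random_family(rng, n=20)
        model = fpca_fit(ts, K=len(GRID))
        X = ts.curve_matrix()
        C = np.cov(X, rowvar=False, ddof=1)
        total = float(model.weights @ np.diag(C))
        assert model.eigenvalues.sum() == pytest.approx(total, abs=1e-8)
        assert model.total_variance == pytest.approx(total, abs=1e-12)

    def test_uniform_weights_match_matrix_pca(self, rng):
        sk = pytest.importorskip("sklearn.decomposition")
        ts = random_family(rng, n=25)
        model = fpca_fit(ts, K=4, weights="uniform")
        pca = sk.PCA(n_components=4).fit(ts.curve_matrix())
        np.testing.assert_allclose(
            model.eigenvalues, pca.explained_variance_, atol=1e-8
        )

    def test_sign_convention_positive_weighted_mass(self, rng):
        model = fpca_fit(random_family(rng, n=10), K=4)
        masses = model.eigenfunctions @ model.weights
        scale = np.abs(model.eigenfunctions).max()
        assert np.all(masses >= -1e-9 * scale)

    @pytest.mark.parametrize("n, K", [(1, 1), (5, 5), (5, 7)])
    def test_size_contracts(self, rng, n, K):
        with pytest.raises(FPCAError):
            fpca_fit(random_family(rng, n=max(n, 1)), K=K)


class TestScores:
    def test_mean_curve_scores_zero_and_centering(self, rng):
        ts = random_family(rng, n=10)
        model = fpca_fit(ts, K=3)
        scores = fpca_scores(model, ts)
        cols = scores[["FPCA1", "FPCA2", "FPCA3"]].to_numpy()
        scale = np.abs(cols).max()
        assert np.abs(cols.mean(axis=0)).max() <= 1e-8 * max(scale, 1.0)
        mean_ts = family_from_matrix(model.mean_curve[None, :].repeat(2, axis=0))
        np.testing.assert_allclose(
            fpca_scores(model, mean_ts)[["FPCA1", "FPCA2", "FPCA3"]], 0.0, atol=1e-9
        )

    def test_single_component_projection(self, rng):
        ts = random_family(rng, n=10)
        model = fpca_fit(ts, K=2)
        c = 3.7
        shifted = family_from_matrix(
            (model.mean_curve + c * model.eigenfunctions[0])[None, :]
        )
        s = fpca_scores(model, shifted)
        assert s.loc[0, "FPCA1"] == pytest.approx(c, abs=1e-9)
        assert s.loc[0, "FPCA2"] == pytest.approx(0.0, abs=1e-9)

    def test_grid_mismatch_rejected(self, rng):
        model = fpca_fit(random_family(rng, n=6), K=2)
        other = family_from_matrix(np.zeros((3, 4)), grid=[0.0, 1.0, 2.0, 3.0])
        with pytest.raises(FPCAError, match="grid mismatch"):
            fpca_scores(model, other)


class TestReconstruct:
    def test_zero_components_gives_mean(self, rng):
        ts = random_family(rng, n=8)
        model = fpca_fit(ts, K=2)
        scores = fpca_scores(model, ts)
        rec = reconstruct(model, scores, N=0)
        for tr in rec:
            np.testing.assert_allclose(tr.distances, model.mean_curve, atol=1e-12)

    def test_full_rank_reconstruction_and_monotone_error(self, rng):
        ts = random_family(rng, n=20)
        K = len(GRID)
        model = fpca_fit(ts, K=K)
        scores = fpca_scores(model, ts)
        X = ts.curve_matrix()
        errs = []
        for N in range(K + 1):
            Xr = reconstruct(model, scores, N=N).curve_matrix()
            # truncation is an orthogonal projection in the quadrature inner
            # product, so the weighted L2 error is the monotone quantity
            errs.append(float(np.sum((Xr - X) ** 2 * model.weights)))
        assert np.abs(reconstruct(model, scores, N=K).curve_matrix() - X).max() <= 1e-8
        assert all(errs[i + 1] <= errs[i] + 1e-10 for i in range(K))

    def test_n_beyond_k_rejected(self, rng):
        model = fpca_fit(random_family(rng, n=6), K=2)
        scores = fpca_scores(model, random_family(np.random.default_rng(0), n=6))
        with pytest.raises(FPCAError):
            reconstruct(model, scores, N=3)


class TestSimulateFamily:
    def test_cardinality_and_pointwise_formula(self, rng):
        model = fpca_fit(random_family(rng, n=10), K=2)
        fam = simulate_family(model, [-2.0, 0.0, 1.0], [0.5, -0.5])
        assert len(fam) == 6
        single = simulate_family(model, [4.2], [0.0])
        np.testing.assert_allclose(
            single.trajectories[0].distances,
            model.mean_curve + 4.2 * model.eigenfunctions[0],
            atol=1e-12,
        )
        mean_only = simulate_family(model, [0.0], [0.0])
        np.testing.assert_allclose(
            mean_only.trajectories[0].distances, model.mean_curve, atol=1e-12
        )

    def test_roundtrip_scores_recover_grid(self, rng):
        model = fpca_fit(random_family(rng, n=12), K=2)
        a_grid, b_grid = [-25.0, -6.0, 4.0], [-16.0, -4.0, 4.0]
        fam = simulate_family(model, a_grid, b_grid)
        scores = fpca_scores(model, fam)[["FPCA1", "FPCA2"]].to_numpy()
        expected = np.array([(a, b) for a in a_grid for b in b_grid])
        np.testing.assert_allclose(scores, expected, atol=1e-8)

    def test_requires_two_components(self, rng):
        model = fpca_fit(random_family(rng, n=10), K=1)
        with pytest.raises(FPCAError, match="K >= 2"):
            simulate_family(model, [0.0], [0.0])


class TestParameterRecovery:
    def test_known_spectrum_recovered_across_seeds(self):
        # n=200 noise-free curves from two components with score variances
        # (4, 1): the fit must recover explained fractions (0.8, 0.2) and the
        # individual scores up to sign
        for seed in range(20):
            ts, true_scores, _, _ = generate_fpca_family(n=200, seed=seed)
            model = fpca_fit(ts, K=2)
            np.testing.assert_allclose(
                model.explained_fractions, [0.8, 0.2], atol=0.03
            )
            got = fpca_scores(model, ts)[["FPCA1", "FPCA2"]].to_numpy()
            for k in range(2):
                corr = np.corrcoef(got[:, k], true_scores[:, k])[0, 1]
                assert abs(corr) >= 0.99


class TestCorrelationsAndSummaries:
    def test_affine_distance_gives_unit_correlation(self, rng):
        ts = random_family(rng, n=10)
        model = fpca_fit(ts, K=2)
        scores = fpca_scores(model, ts)
        xi1 = scores["FPCA1"].to_numpy()
        X = 2.0 * xi1[:, None] + 5.0 + np.zeros((1, len(GRID)))
        affine = TrajectorySet(
            [Trajectory(s, c, GRID, X[i]) for i, (s, c) in enumerate(ts.labels())],
            grid=GRID,
        )
        corr = score_distance_correlation(scores, affine)
        np.testing.assert_allclose(corr["FPCA1"], 1.0, atol=1e-12)

    def test_constant_distance_cell_missing(self, rng):
        ts = random_family(rng, n=8)
        model = fpca_fit(ts, K=2)
        scores = fpca_scores(model, ts)
        X = ts.curve_matrix().copy()
        X[:, 2] = 7.0
        const = TrajectorySet(
            [Trajectory(s, c, GRID, X[i]) for i, (s, c) in enumerate(ts.labels())],
            grid=GRID,
        )
        corr = score_distance_correlation(scores, const)
        assert np.isnan(corr.iloc[2]["FPCA1"])

    def test_matches_scipy_pearson(self, rng):
        from scipy.stats import pearsonr

        ts = random_family(rng, n=9)
        model = fpca_fit(ts, K=2)
        scores = fpca_scores(model, ts)
        corr = score_distance_correlation(scores, ts)
        X = ts.curve_matrix()
        for k, col in enumerate(["FPCA1", "FPCA2"]):
            for j in range(len(GRID)):
                expected = pearsonr(scores[col], X[:, j]).statistic
                assert corr.iloc[j][col] == pytest.approx(expected, abs=1e-12)

    def test_too_few_trajectories(self, rng):
        ts = random_family(rng, n=2)
        model = fpca_fit(ts, K=1)
        with pytest.raises(FPCAError, match="three"):
            score_distance_correlation(fpca_scores(model, ts), ts)

    def test_group_summary_hand_example(self):
        scores = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c"],
                "condition": ["g1", "g1", "g2"],
                "FPCA1": [-1.0, 1.0, 3.0],
            }
        )
        out = score_group_summary(scores)
        g1 = out[(out["condition"] == "g1") & (out["score"] == "FPCA1")].iloc[0]
        assert g1["mean"] == 0.0
        assert g1["sd"] == pytest.approx(np.sqrt(2))
        g2 = out[(out["condition"] == "g2") & (out["score"] == "FPCA1")].iloc[0]
        assert np.isnan(g2["sd"])  # singleton group
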