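"""Tests for age-weighted PCA+ICA mode discovery and its null calibrations."""

from __future__ import annotations

import numpy as np
import pytest

from brainmodes.modes import (
    age_weight,
    finalize_modes,
    group_reduce,
    null_max_correlation,
    null_weighting_test,
    pair_components,
    pair_matrix,
    pca_reduce,
    run_ica,
    split_half_reproducibility,
    sweep_dimensionality,
)
from brainmodes.utils import abs_corr_matrix


class TestAgeWeight:
    def test_uncorrelated_column_scaled_by_floor(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(45, 80, 500)
        ac = age - age.mean()
        col = rng.standard_normal(500)
        col -= ac * (col @ ac) / (ac @ ac)  # exactly orthogonal to age
        weighted, w = age_weight(col[:, None], age)
        assert w[0] == pytest.approx(0.1, abs=1e-12)
        np.testing.assert_allclose(weighted[:, 0], 0.1 * col)

    def test_age_itself_scaled_by_one_point_one(self):
        age = np.linspace(45, 80, 100)
        _, w = age_weight(age[:, None], age)
        assert w[0] == pytest.approx(1.1, abs=1e-12)

    def test_zero_variance_column_floored_with_warning(self):
        age = np.linspace(45, 80, 50)
        with pytest.warns(UserWarning, match="zero-variance"):
            _, w = age_weight(np.ones((50, 1)), age)
        assert w[0] == pytest.approx(0.1)


class TestPCA:
    def test_rank2_matrix_reconstructed_at_d2(self):
        rng = np.random.default_rng(1)
        m = rng.standard_normal((50, 2)) @ rng.standard_normal((2, 30))
        pca = pca_reduce(m, 2)
        recon = pca.basis @ pca.coords + pca.column_means
        assert np.linalg.norm(recon - m) / np.linalg.norm(m) < 1e-8

    def test_full_rank_explains_everything(self):
        rng = np.random.default_rng(2)
        m = rng.standard_normal((20, 8))
        pca = pca_reduce(m, 8)
        assert pca.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert (np.diff(pca.eigenvalues) <= 1e-9).all()

    def test_planted_modes_dominate_eigenspectrum(self, study):
        pca = pca_reduce(study["dense"], 10)
        ev = pca.eigenvalues
        assert ev[4] / ev[5] > 2.0  # eigen-gap after the 5 planted modes

    def test_out_of_range_dim_errors(self):
        with pytest.raises(ValueError):
            pca_reduce(np.zeros((5, 3)), 4)


class TestICA:
    def test_recovers_mixed_laplacian_sources(self):
        rng = np.random.default_rng(3)
        sources = rng.laplace(size=(2, 5000))
        mixed = rng.standard_normal((2, 2)) @ sources
        # mimic the pipeline: treat mixed rows as the d-dim coordinates
        from brainmodes.modes import PCAResult

        pca = PCAResult(np.eye(2), mixed, np.ones(2), np.zeros(5000))
        ica = run_ica(pca, 2, rng_seed=0)
        c = abs_corr_matrix(sources, ica.idp_weights)
        assert c.max(axis=1).min() > 0.99

    def test_same_seed_reproducible(self, study):
        pca = pca_reduce(study["dense"], 5)
        a = run_ica(pca, 5, rng_seed=42)
        b = run_ica(pca, 5, rng_seed=42)
        np.testing.assert_array_equal(a.idp_weights, b.idp_weights)

    def test_source_vectors_orthogonal(self, study):
        pca = pca_reduce(study["dense"], 6)
        ica = run_ica(pca, 6, rng_seed=1)
        w = ica.idp_weights - ica.idp_weights.mean(axis=1, keepdims=True)
        g = w @ w.T
        norms = np.sqrt(np.diag(g))
        cos = g / np.outer(norms, norms) - np.eye(6)
        assert np.abs(cos).max() < 1e-3


class TestPairing:
    def test_greedy_trace_simple(self):
        c = np.array([[0.9, 0.2], [0.8, 0.85]])
        pairs, scores = pair_matrix(c)
        assert pairs == [(0, 0), (1, 1)]
        np.testing.assert_allclose(scores, [0.9, 0.85])

    def test_greedy_can_be_suboptimal(self):
        # documented greedy behaviour: (A1,B1)=0.9 locks A2 into 0.1
        c = np.array([[0.9, 0.85], [0.89, 0.1]])
        pairs, scores = pair_matrix(c)
        assert pairs == [(0, 0), (1, 1)]
        np.testing.assert_allclose(scores, [0.9, 0.1])
        pairs_opt, scores_opt = pair_matrix(c, method="hungarian")
        assert set(pairs_opt) == {(1, 0), (0, 1)}
        assert scores_opt.sum() > scores.sum()

    def test_identical_sets_identity_pairing(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((4, 100))
        pairs, scores = pair_components(a, a.copy())
        assert sorted(pairs) == [(i, i) for i in range(4)]
        np.testing.assert_allclose(scores, 1.0, atol=1e-12)

    def test_empty_sets(self):
        pairs, scores = pair_components(np.empty((0, 5)), np.empty((0, 5)))
        assert pairs == [] and scores.size == 0


class TestSplitHalf:
    def test_planted_modes_counted(self, discovered):
        weighted = discovered["weighted"]
        count, _ = split_half_reproducibility(weighted, 8, n_splits=3, rng_seed=0)
        assert abs(count - 5) <= 1

    def test_pure_noise_yields_zero(self):
        rng = np.random.default_rng(6)
        noise = rng.standard_normal((600, 100))
        count, _ = split_half_reproducibility(noise, 8, n_splits=3, rng_seed=1)
        assert count == 0.0

    def test_impossible_threshold_yields_zero(self, discovered):
        count, _ = split_half_reproducibility(
            discovered["weighted"], 6, n_splits=2, r_thresh=1.0, rng_seed=2
        )
        assert count == 0.0

    def test_dim_beyond_half_rank_errors(self):
        with pytest.raises(ValueError):
            split_half_reproducibility(np.zeros((20, 100)), 15)


class TestSweepAndFinalize:
    def test_sweep_finds_informative_dim(self, discovered):
        report = discovered["report"]
        assert report.counts[report.chosen_dim] >= 4.5
        assert all(c <= d for d, c in report.counts.items())

    def test_single_dim_range(self, discovered):
        report = sweep_dimensionality(
            discovered["weighted"], [6], n_splits=2, rng_seed=9
        )
        assert report.chosen_dim == 6

    def test_modes_oriented_and_ordered(self, study, discovered):
        modes = discovered["modes"]
        age = study["age"]
        for i in range(modes.n_modes):
            assert np.corrcoef(modes.subject_weights[:, i], age)[0, 1] >= 0
        assert (np.diff(modes.order_statistic) <= 1e-12).all()

    def test_planted_recovery(self, study, discovered):
        c = abs_corr_matrix(study["truth"].true_idp_weights, discovered["modes"].idp_weights)
        assert c.max(axis=1).min() > 0.9

    def test_rerun_same_seed_identical(self, study, discovered):
        again = finalize_modes(
            discovered["weighted"], study["dense"], discovered["report"].chosen_dim,
            study["age"], n_runs=30, rng_seed=1,
        )
        np.testing.assert_allclose(
            again.idp_weights, discovered["modes"].idp_weights, atol=1e-6
        )

    def test_empty_range_errors(self, discovered):
        with pytest.raises(ValueError):
            sweep_dimensionality(discovered["weighted"], [])


class TestSubjectWeightProjection:
    def test_reproduces_finalized_weights(self, study, discovered):
        from brainmodes.modes import project_subject_weights

        modes = discovered["modes"]
        sw = project_subject_weights(study["dense"], modes.idp_weights)
        np.testing.assert_allclose(sw, modes.subject_weights, atol=1e-8)

    def test_sex_retaining_projection_keeps_sex_signal(self, study, discovered):
        from brainmodes.containers import ConfoundTable
        from brainmodes.modes import project_subject_weights
        from brainmodes.preprocess import deconfound, impute_missing_noise

        clean = study["clean"]
        conf = study["confounds"].frame.loc[clean.subject_ids]
        sex = conf["sex"].to_numpy()
        no_sex = ConfoundTable(conf.drop(columns=["sex"]))
        dense_keep_sex = deconfound(
            impute_missing_noise(clean, rng_seed=1), no_sex
        )
        sw_all = project_subject_weights(study["dense"], discovered["modes"].idp_weights)
        sw_sexed = project_subject_weights(dense_keep_sex, discovered["modes"].idp_weights)
        # sex-related variance survives only the sex-retaining pathway
        gap_sexed = max(
            abs(sw_sexed[sex == 0, i].mean() - sw_sexed[sex == 1, i].mean())
            for i in range(sw_sexed.shape[1])
        )
        gap_all = max(
            abs(sw_all[sex == 0, i].mean() - sw_all[sex == 1, i].mean())
            for i in range(sw_all.shape[1])
        )
        assert gap_sexed > gap_all


class TestNullCalibrations:
    def test_single_vector_percentile_matches_fisher_z(self):
        # 90th pct of |r| at n=62: tanh(1.6449/sqrt(59)) ~ 0.211
        out = null_max_correlation(62, 1, 20_000, rng_seed=0, percentiles=(90.0,))
        assert out["percentiles"][90.0] == pytest.approx(np.tanh(1.6449 / np.sqrt(59)), abs=0.01)

    def test_percentile_monotonicity(self):
        out = null_max_correlation(30, 8, 2000, rng_seed=1)
        assert out["percentiles"][50.0] <= out["percentiles"][90.0] <= out["max"]

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            null_max_correlation(2, 5, 10)

    def test_weighting_null_scale(self):
        # sd of null r is ~1/sqrt(n): at n=4000 a single draw stays tiny
        r = null_weighting_test(4000, 1, 1, rng_seed=2)
        assert r < 0.06

    def test_weighting_null_shrinks_with_sqrt_n(self):
        a = null_weighting_test(1000, 64, 20, rng_seed=3)
        b = null_weighting_test(4000, 64, 20, rng_seed=4)
        assert 1.5 < a / b < 2.7  # expected factor 2


class TestGroupReduce:
    def test_identical_columns_single_pseudo_idp(self):
        rng = np.random.default_rng(7)
        col = rng.standard_normal(6)
        weights = np.tile(col[:, None], (1, 10))
        out = group_reduce(weights, ["g"] * 10, rng_seed=0)
        assert out["g"].shape[1] == 1
        assert abs_corr_matrix(col[None, :], out["g"].T)[0, 0] > 0.99

    def test_every_group_keeps_at_least_one(self, discovered):
        modes = discovered["modes"]
        groups = ["a"] * 100 + ["b"] * 50 + ["c"] * 50
        out = group_reduce(modes.idp_weights, groups, rng_seed=1)
        assert set(out) == {"a", "b", "c"}
        assert all(v.shape[1] >= 1 for v in out.values())

    def test_single_idp_group_passthrough(self):
        w = np.arange(8.0).reshape(4, 2)
        out = group_reduce(w, ["a", "b"], rng_seed=2)
        np.testing.assert_array_equal(out["a"], w[:, :1])

    def test_two_planted_patterns_recovered(self):
        rng = np.random.default_rng(8)
        n_modes, nj = 40, 30
        p1, p2 = np.linalg.qr(rng.standard_normal((n_modes, 2)))[0].T
        loadings = rng.laplace(size=(2, nj))
        block = np.column_stack([np.outer(p1, loadings[0]), np.outer(p2, loadings[1])])
        block += 0.02 * rng.standard_normal(block.shape)
        out = group_reduce(block, ["g"] * (2 * nj), rng_seed=3)
        c = abs_corr_matrix(np.vstack([p1, p2]), out["g"].T)
        assert out["g"].shape[1] == 2
        assert c.max(axis=1).min() > 0.9
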