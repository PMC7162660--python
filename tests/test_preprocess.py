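"""Unit and property tests for the IDP cleaning pipeline."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtri

from brainmodes.containers import ConfoundTable, IDPMatrix
from brainmodes.preprocess import (
    deconfound,
    filter_subjects_by_missingness,
    impute_missing_noise,
    quantile_normalise,
    remove_outliers_mad,
    with_age_confounds,
)

import pandas as pd


def _idp(values, mask=None):
    values = np.asarray(values, float)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    n, p = values.shape
    return IDPMatrix(
        values, mask, [f"s{i}" for i in range(n)], [f"i{j}" for j in range(p)], ["g"] * p
    )


class TestOutlierRemoval:
    def test_gross_outlier_flagged_by_six_mad_rule(self):
        # median 6, MAD 3 -> fence at 6 +/- 18; only the 1000 trips it
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 1000], dtype=float)
        _, mask = remove_outliers_mad(x, k=6)
        assert mask.tolist() == [False] * 10 + [True]

    def test_constant_column_unchanged(self):
        x = np.array([5.0, 5.0, 5.0, 5.0])
        with pytest.warns(UserWarning, match="MAD is zero"):
            _, mask = remove_outliers_mad(x)
        assert not mask.any()

    def test_gaussian_column_rarely_flagged(self):
        # 6 x MAD ~ 4.05 sigma for a Gaussian: two-sided tail ~ 5e-5
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10_000)
        _, mask = remove_outliers_mad(x)
        assert mask.sum() <= 4

    def test_existing_missing_preserved_and_ignored(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 1e6])
        mask = np.array([False, False, False, False, True])
        _, out = remove_outliers_mad(x, mask)
        assert out.tolist() == mask.tolist()

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            remove_outliers_mad(np.array([1.0, 2.0]), np.array([True, True]))


class TestQuantileNormalise:
    def test_blom_scores_for_three_values(self):
        out = quantile_normalise(np.array([3.0, 1.0, 2.0]))
        expected = ndtri((np.array([3, 1, 2]) - 3 / 8) / (3 + 1 / 4))
        np.testing.assert_allclose(out, expected, atol=1e-12)
        np.testing.assert_allclose(out, [0.8694, -0.8694, 0.0], atol=5e-4)

    def test_monotone_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        np.testing.assert_allclose(quantile_normalise(np.exp(x)), quantile_normalise(x))

    def test_antisymmetric_for_symmetric_input(self):
        out = quantile_normalise(np.array([-2.0, 0.0, 2.0]))
        assert out[1] == 0.0
        assert out[0] == -out[2]

    def test_moments_near_standard_gaussian(self):
        rng = np.random.default_rng(2)
        out = quantile_normalise(rng.exponential(size=500))
        assert abs(out.mean()) < 0.01
        assert abs(out.std() - 1.0) < 0.05

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError):
            quantile_normalise(np.array([1.0, 2.0]))

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False),
            min_size=3,
            max_size=40,
            unique=True,
        )
    )
    def test_rank_order_preserved(self, values):
        x = np.asarray(values)
        out = quantile_normalise(x)
        np.testing.assert_array_equal(np.argsort(out), np.argsort(x))


class TestSubjectFilter:
    def test_boundary_at_exactly_max_missing(self):
        mask = np.zeros((3, 60), dtype=bool)
        mask[0, :50] = True  # exactly 50 -> dropped
        mask[1, :49] = True  # 49 -> kept
        reduced, dropped = filter_subjects_by_missingness(_idp(np.ones((3, 60)), mask))
        assert dropped == ["s0"]
        assert reduced.subject_ids == ["s1", "s2"]

    def test_no_missing_is_identity(self):
        m = _idp(np.arange(12.0).reshape(3, 4))
        reduced, dropped = filter_subjects_by_missingness(m)
        assert dropped == []
        np.testing.assert_array_equal(reduced.values, m.values)

    def test_all_dropped_gives_empty_matrix(self):
        mask = np.ones((2, 60), dtype=bool)
        with pytest.warns(UserWarning, match="all subjects"):
            reduced, dropped = filter_subjects_by_missingness(_idp(np.ones((2, 60)), mask))
        assert reduced.n_subjects == 0
        assert len(dropped) == 2


class TestNoiseFill:
    def test_identity_without_missing(self):
        m = _idp(np.arange(6.0).reshape(2, 3))
        np.testing.assert_array_equal(impute_missing_noise(m, rng_seed=0), m.values)

    def test_fill_scale(self):
        rng = np.random.default_rng(3)
        mask = rng.random((200, 100)) < 0.5
        m = _idp(np.zeros((200, 100)), mask)
        filled = impute_missing_noise(m, sd=0.01, rng_seed=4)
        fills = filled[mask]
        assert fills.size > 9000
        assert abs(fills.std() - 0.01) < 0.001

    def test_seed_determinism(self):
        mask = np.eye(5, dtype=bool)
        m = _idp(np.zeros((5, 5)), mask)
        np.testing.assert_array_equal(
            impute_missing_noise(m, rng_seed=7), impute_missing_noise(m, rng_seed=7)
        )


class TestDeconfound:
    def test_confound_column_removed_entirely(self):
        rng = np.random.default_rng(5)
        conf = rng.standard_normal((100, 1))
        resid = deconfound(conf.copy(), conf)
        assert np.abs(resid).max() < 1e-10

    def test_orthogonal_data_unchanged(self):
        rng = np.random.default_rng(6)
        conf = rng.standard_normal((200, 2))
        data = rng.standard_normal((200, 3))
        # orthogonalise data to conf and intercept first
        design = np.column_stack([np.ones(200), conf])
        data -= design @ np.linalg.lstsq(design, data, rcond=None)[0]
        np.testing.assert_allclose(deconfound(data, conf), data, atol=1e-10)

    def test_residual_recovers_independent_noise(self):
        rng = np.random.default_rng(7)
        conf = rng.standard_normal((1000, 1))
        noise = rng.standard_normal(1000)
        data = (conf[:, 0] * 2.0 + noise)[:, None]
        resid = deconfound(data, conf)[:, 0]
        assert np.corrcoef(resid, noise)[0, 1] > 0.99

    def test_residuals_orthogonal_to_confounds(self):
        rng = np.random.default_rng(8)
        conf = rng.standard_normal((300, 4))
        data = rng.standard_normal((300, 6)) + conf @ rng.standard_normal((4, 6))
        resid = deconfound(data, conf)
        inner = np.abs(conf.T @ resid)
        bound = 1e-8 * np.linalg.norm(conf, axis=0)[:, None] * np.linalg.norm(resid, axis=0)
        assert (inner < np.maximum(bound, 1e-10)).all()

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        conf = rng.standard_normal((300, 3))
        data = rng.standard_normal((300, 5))
        once = deconfound(data, conf)
        twice = deconfound(once, conf)
        assert np.linalg.norm(twice - once) < 1e-6

    def test_sex_separated_orthogonal_within_each_sex(self):
        rng = np.random.default_rng(10)
        sex = rng.integers(0, 2, 400)
        conf = rng.standard_normal((400, 2))
        data = rng.standard_normal((400, 3))
        resid = deconfound(data, conf, sex_separated=True, sex=sex)
        for level in (0, 1):
            sub = sex == level
            inner = np.abs(conf[sub].T @ resid[sub])
            assert inner.max() < 1e-6

    def test_age_related_flag_controls_columns(self):
        rng = np.random.default_rng(11)
        age = rng.uniform(45, 80, 300)
        frame = pd.DataFrame({"head_size": rng.standard_normal(300)})
        table = with_age_confounds(ConfoundTable(frame), age)
        data = (age - age.mean())[:, None] * 1.0
        kept = deconfound(data, table, include_age_related=False)
        removed = deconfound(data, table, include_age_related=True)
        assert np.std(kept) > 0.5 * np.std(data)  # age signal survives
        assert np.abs(removed).max() < 1e-8  # nIDP pathway removes it

    def test_mismatched_subjects_error(self):
        with pytest.raises(ValueError):
            deconfound(np.zeros((5, 2)), np.zeros((4, 1)))


class TestFullPipeline:
    def test_columns_centred_and_deconfounded(self, study):
        dense = study["dense"]
        conf = study["confounds"].frame.loc[study["clean"].subject_ids].to_numpy(float)
        assert np.abs(dense.mean(axis=0)).max() < 0.05
        inner = np.abs(conf.T @ dense)
        bound = np.linalg.norm(conf, axis=0)[:, None] * np.linalg.norm(dense, axis=0)
        assert (inner <= 1e-8 * bound + 1e-9).all()

    def test_outliers_marked_missing(self, study):
        # injected outliers sit 8-12 column SDs out: none survive cleaning
        clean = study["clean"]
        present = ~clean.missing_mask
        assert np.abs(clean.values[present]).max() < 6.0
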