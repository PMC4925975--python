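"""Tests for the graded-response-model data generator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from difpower import (
    ItemBank,
    TRAIT_CONDITIONS,
    generate_responses,
    grm_category_probabilities,
    inject_uniform_dif,
    sample_item_parameters,
    sample_latent_traits,
)
from difpower.grm import InvalidScenarioError


class TestCategoryProbabilities:
    @pytest.mark.parametrize(
        "theta,a,thresholds,expected",
        [
            # at the threshold the logistic is exactly 1/2
            (0.0, 1.0, [0.0], [0.5, 0.5]),
            # direct evaluation: logistic(1)=0.73106, logistic(-1)=0.26894
            (0.0, 1.0, [-1.0, 1.0], [0.26894, 0.46212, 0.26894]),
        ],
    )
    def test_known_values(self, theta, a, thresholds, expected):
        p = grm_category_probabilities(theta, a, np.array(thresholds))
        np.testing.assert_allclose(p, expected, atol=5e-6)

    @given(
        theta=st.floats(-6, 6),
        a=st.floats(0.2, 3.0),
        cuts=st.lists(st.floats(-4, 4), min_size=1, max_size=6, unique=True),
    )
    @settings(max_examples=200, deadline=None)
    def test_valid_distribution(self, theta, a, cuts):
        p = grm_category_probabilities(theta, a, np.sort(np.array(cuts)))
        assert np.all(p >= 0)
        assert math.isclose(p.sum(), 1.0, abs_tol=1e-12)

    def test_cumulative_monotone_in_theta_and_category(self):
        thetas = np.linspace(-4, 4, 41)
        b = np.array([-1.2, -0.1, 0.7, 1.9])
        cum = expit(1.1 * (thetas[:, None] - b))
        assert np.all(np.diff(cum, axis=0) > 0)  # increasing in theta
        assert np.all(np.diff(cum, axis=1) < 0)  # decreasing in category

    def test_rejects_unsorted_thresholds(self):
        with pytest.raises(InvalidScenarioError):
            grm_category_probabilities(0.0, 1.0, np.array([1.0, -1.0]))


class TestItemParameters:
    def test_ranges_and_shapes(self, rng):
        bank = sample_item_parameters(10, 5, rng)
        assert bank.n_items == 10 and bank.n_categories == 5
        assert np.all((bank.discrimination > 0.5) & (bank.discrimination < 1.5))
        assert bank.thresholds.shape == (10, 4)
        assert np.all(np.diff(bank.thresholds, axis=1) > 0)

    def test_single_threshold_case(self, rng):
        bank = sample_item_parameters(1, 2, rng)
        assert bank.thresholds.shape == (1, 1)

    def test_deterministic_given_seed(self):
        b1 = sample_item_parameters(10, 3, np.random.default_rng(7))
        b2 = sample_item_parameters(10, 3, np.random.default_rng(7))
        np.testing.assert_array_equal(b1.discrimination, b2.discrimination)
        np.testing.assert_array_equal(b1.thresholds, b2.thresholds)

    def test_too_few_categories(self, rng):
        with pytest.raises(InvalidScenarioError):
            sample_item_parameters(10, 1, rng)

    def test_csv_roundtrip(self, rng, tmp_path):
        bank = sample_item_parameters(10, 4, rng)
        path = tmp_path / "bank.csv"
        bank.to_csv(path)
        back = ItemBank.from_csv(path)
        np.testing.assert_allclose(back.discrimination, bank.discrimination)
        np.testing.assert_allclose(back.thresholds, bank.thresholds)


class TestTraitDistributions:
    def test_condition_table(self):
        assert set(TRAIT_CONDITIONS) == set(range(1, 10))
        c1 = TRAIT_CONDITIONS[1]
        assert c1.reference_dist.kind == "normal"
        assert c1.focal_dist.kind == "normal"
        c9 = TRAIT_CONDITIONS[9]
        assert (c9.reference_dist.alpha, c9.reference_dist.beta) == (4, 0.5)
        assert (c9.focal_dist.alpha, c9.focal_dist.beta) == (0.5, 4)
        pairs = {
            (c.reference_dist.alpha, c.reference_dist.beta)
            for c in TRAIT_CONDITIONS.values()
            if c.reference_dist.kind == "beta"
        } | {
            (c.focal_dist.alpha, c.focal_dist.beta)
            for c in TRAIT_CONDITIONS.values()
            if c.focal_dist.kind == "beta"
        }
        assert pairs == {(1, 4), (0.5, 4), (4, 1), (4, 0.5)}

    def test_standardized_beta_moments(self, rng):
        theta, _ = sample_latent_traits(TRAIT_CONDITIONS[3], 100_000, 1, rng)
        assert abs(theta.mean()) < 0.02
        assert abs(theta.var() - 1.0) < 0.02

    def test_condition3_skewness(self, rng):
        # closed-form beta skewness at (0.5, 4); standardization is affine
        a, b = 0.5, 4.0
        expected = 2 * (b - a) * math.sqrt(a + b + 1) / ((a + b + 2) * math.sqrt(a * b))
        ref, foc = sample_latent_traits(TRAIT_CONDITIONS[3], 200_000, 200_000, rng)
        for theta in (ref, foc):
            z = (theta - theta.mean()) / theta.std()
            assert abs((z**3).mean() - expected) < 0.05
        assert abs(expected - 1.7859) < 1e-3

    def test_normal_condition_mean(self, rng):
        ref, foc = sample_latent_traits(TRAIT_CONDITIONS[1], 300, 300, rng)
        assert abs(ref.mean()) < 3 / math.sqrt(300)
        assert len(foc) == 300

    def test_unknown_condition(self, rng):
        with pytest.raises(InvalidScenarioError):
            sample_latent_traits(12, 10, 10, rng)


class TestUniformDif:
    def test_zero_shift_is_identity(self, small_bank):
        out = inject_uniform_dif(small_bank, 1, 0.0)
        np.testing.assert_array_equal(out.thresholds, small_bank.thresholds)

    @pytest.mark.parametrize("delta", [0.5, -0.5, 1.0])
    def test_exact_shift_one_item(self, small_bank, delta):
        out = inject_uniform_dif(small_bank, 0, delta)
        np.testing.assert_allclose(
            out.thresholds[0], small_bank.thresholds[0] + delta
        )
        np.testing.assert_array_equal(out.thresholds[1:], small_bank.thresholds[1:])
        np.testing.assert_array_equal(out.discrimination, small_bank.discrimination)

    def test_shift_roundtrip_restores_bank(self, small_bank):
        out = inject_uniform_dif(inject_uniform_dif(small_bank, 2, 0.7), 2, -0.7)
        np.testing.assert_allclose(out.thresholds, small_bank.thresholds, atol=1e-15)

    def test_bad_index(self, small_bank):
        with pytest.raises(IndexError):
            inject_uniform_dif(small_bank, 99, 0.5)

    def test_positive_shift_lowers_expected_score(self, small_bank):
        # at theta = 0, shifting thresholds up must lower E[score]
        cats = np.arange(1, small_bank.n_categories + 1)
        shifted = inject_uniform_dif(small_bank, 0, 0.5)
        for bank_pair in [(small_bank, shifted)]:
            e_ref = cats @ grm_category_probabilities(
                0.0, bank_pair[0].discrimination[0], bank_pair[0].thresholds[0]
            )
            e_foc = cats @ grm_category_probabilities(
                0.0, bank_pair[1].discrimination[0], bank_pair[1].thresholds[0]
            )
            assert e_foc < e_ref


class TestResponseGeneration:
    def test_extreme_theta_saturates(self, small_bank, rng):
        hi = generate_responses(
            np.full(20, 20.0), np.full(20, 20.0), small_bank, small_bank, rng
        )
        assert np.all(hi.responses == small_bank.n_categories)
        lo = generate_responses(
            np.full(20, -20.0), np.full(20, -20.0), small_bank, small_bank, rng
        )
        assert np.all(lo.responses == 1)

    def test_group_labels_and_total_score(self, small_bank, rng):
        data = generate_responses(
            np.zeros(30), np.zeros(20), small_bank, small_bank, rng
        )
        assert data.n_subjects == 50
        assert data.group.sum() == 20
        np.testing.assert_array_equal(data.total_score, data.responses.sum(axis=1))
        assert np.all(data.total_score >= data.n_items)
        assert np.all(data.total_score <= data.n_items * small_bank.n_categories)

    def test_empirical_frequencies_match_model(self, rng):
        # Monte-Carlo oracle: per-item category frequencies must match the
        # average of the model probabilities over the same trait draws
        bank = sample_item_parameters(10, 3, rng)
        theta_ref, theta_foc = sample_latent_traits(TRAIT_CONDITIONS[1], 5000, 5000, rng)
        data = generate_responses(theta_ref, theta_foc, bank, bank, rng)
        theta = np.concatenate([theta_ref, theta_foc])
        n = len(theta)
        for i in range(bank.n_items):
            probs = grm_category_probabilities(
                theta, bank.discrimination[i], bank.thresholds[i]
            ).mean(axis=0)
            for j in range(bank.n_categories):
                freq = np.mean(data.responses[:, i] == j + 1)
                se = math.sqrt(probs[j] * (1 - probs[j]) / n)
                assert abs(freq - probs[j]) < 3 * se + 1e-9

    def test_mismatched_banks_rejected(self, small_bank, rng):
        other = ItemBank(np.ones(2), np.array([[-1.0, 0.5], [0.0, 1.0]]))
        with pytest.raises(InvalidScenarioError):
            generate_responses(np.zeros(5), np.zeros(5), small_bank, other, rng)

    def test_csv_roundtrip(self, small_bank, rng, tmp_path):
        from difpower import ResponseData

        data = generate_responses(np.zeros(10), np.ones(5), small_bank, small_bank, rng)
        path = tmp_path / "resp.csv"
        data.to_csv(path)
        back = ResponseData.from_csv(path)
        np.testing.assert_array_equal(back.responses, data.responses)
        np.testing.assert_array_equal(back.group, data.group)
        np.testing.assert_array_equal(back.total_score, data.total_score)
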