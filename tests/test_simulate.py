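"""Multilevel GRM generator: parameter ranges, balance, GRM probabilities."""

import numpy as np
import pytest

from polydif.simulate import (
    HIGH_DISCRIMINATION,
    LOW_DISCRIMINATION,
    AbilitySample,
    ItemBank,
    assign_groups,
    category_probabilities,
    generate_responses,
    sample_abilities,
    sample_item_bank,
    simulate_dataset,
)

from _oracles import anova_icc, grm_category_probs, logistic


class TestItemBank:
    def test_discriminations_within_range(self):
        for rng_pair in (LOW_DISCRIMINATION, HIGH_DISCRIMINATION):
            bank = sample_item_bank(16, disc_range=rng_pair,
                                    rng=np.random.default_rng(1))
            assert bank.discrimination.shape == (16,)
            assert np.all(bank.discrimination >= rng_pair[0])
            assert np.all(bank.discrimination <= rng_pair[1])

    def test_thresholds_ordered_and_in_interval(self):
        bank = sample_item_bank(16, rng=np.random.default_rng(2))
        assert bank.thresholds.shape == (16, 4)
        assert np.all(np.diff(bank.thresholds, axis=1) > 0)
        assert np.all(np.abs(bank.thresholds) <= 2.5)

    def test_two_categories_give_one_threshold(self):
        bank = sample_item_bank(5, n_categories=2, rng=np.random.default_rng(3))
        assert bank.thresholds.shape == (5, 1)

    def test_deterministic_under_seed(self):
        b1 = sample_item_bank(16, rng=np.random.default_rng(99))
        b2 = sample_item_bank(16, rng=np.random.default_rng(99))
        np.testing.assert_array_equal(b1.discrimination, b2.discrimination)
        np.testing.assert_array_equal(b1.thresholds, b2.thresholds)

    def test_invalid_range_raises(self):
        with pytest.raises(ValueError, match="lo < hi"):
            sample_item_bank(4, disc_range=(1.0, 0.5))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="positive"):
            ItemBank([0.5, -1.0], [[-1, 0, 1, 2]] * 2)
        with pytest.raises(ValueError, match="increasing"):
            ItemBank([0.5], [[0.5, 0.2, 0.7, 1.0]])


class TestAbilities:
    def test_zero_icc_degenerates(self):
        ab = sample_abilities(20, 10, 0.0, rng=np.random.default_rng(4))
        assert np.all(ab.cluster_effect == 0)
        assert abs(ab.theta.var() - 1) < 0.2

    def test_total_variance_one(self):
        ab = sample_abilities(200, 20, 0.05, rng=np.random.default_rng(5))
        # 3 Monte-Carlo SEs of a variance estimate at n=4000
        assert abs(ab.theta.var() - 1.0) < 3 * np.sqrt(2 / 4000)

    def test_anova_icc_recovers_nominal(self):
        ab = sample_abilities(200, 20, 0.45, rng=np.random.default_rng(6))
        assert abs(anova_icc(ab.theta, ab.cluster_id) - 0.45) < 0.05

    @pytest.mark.parametrize("icc", [0.05, 0.25, 0.45])
    def test_icc_recovery_across_levels(self, icc):
        ab = sample_abilities(300, 20, icc, rng=np.random.default_rng(7))
        assert abs(anova_icc(ab.theta, ab.cluster_id) - icc) < 0.06

    def test_invalid_icc_raises(self):
        with pytest.raises(ValueError, match="icc"):
            sample_abilities(10, 5, 1.2)


class TestGroups:
    def test_within_even_size_exact_balance(self):
        g = assign_groups(30, 10, "within", rng=np.random.default_rng(8))
        per_cluster = g.reshape(30, 10).sum(axis=1)
        assert np.all(per_cluster == 5)

    def test_within_odd_size_near_balance(self):
        g = assign_groups(50, 5, "within", rng=np.random.default_rng(9))
        per_cluster = g.reshape(50, 5).sum(axis=1)
        assert set(per_cluster) == {2, 3}
        assert g.sum() == 125  # overall exactly balanced

    def test_between_balance_and_constancy(self):
        g = assign_groups(50, 4, "between", rng=np.random.default_rng(10))
        by_cluster = g.reshape(50, 4)
        assert np.all(by_cluster.std(axis=1) == 0)
        assert by_cluster[:, 0].sum() == 25

    def test_unbalanceable_designs_raise(self):
        with pytest.raises(ValueError):
            assign_groups(51, 5, "within")  # odd x odd
        with pytest.raises(ValueError):
            assign_groups(51, 4, "between")


class TestCategoryProbabilities:
    def test_frozen_logistic_values(self):
        """P(Y>=k) at theta=0, a=1, thresholds (-1,0,1,2)."""
        p = category_probabilities(0.0, 1.0, [-1.0, 0.0, 1.0, 2.0])
        tails = 1 - np.cumsum(p)[:-1]
        np.testing.assert_allclose(
            tails, [0.7311, 0.5, 0.2689, 0.1192], atol=5e-5
        )
        assert p.sum() == pytest.approx(1.0)

    def test_matches_independent_oracle(self):
        r = np.random.default_rng(11)
        for _ in range(20):
            a = r.uniform(0.3, 2.5)
            b = np.sort(r.uniform(-2.5, 2.5, 4))
            theta = r.normal()
            d = r.choice([0.0, 0.4, 0.8])
            np.testing.assert_allclose(
                category_probabilities(theta, a, b, d),
                grm_category_probs(theta, a, b, d),
                atol=1e-12,
            )

    def test_half_probability_at_shifted_threshold(self):
        b = np.array([-0.3, 0.5, 1.0, 1.8])
        for dif in (0.0, 0.8):
            p = category_probabilities(b[0] + dif, 1.7, b, dif)
            assert 1 - p[0] == pytest.approx(0.5, abs=1e-12)

    def test_limits(self):
        p_hi = category_probabilities(40.0, 1.0, [-1.0, 0.0, 1.0, 2.0])
        assert p_hi[-1] == pytest.approx(1.0, abs=1e-10)
        p_lo = category_probabilities(-40.0, 1.0, [-1.0, 0.0, 1.0, 2.0])
        assert p_lo[0] == pytest.approx(1.0, abs=1e-10)

    def test_unordered_thresholds_raise(self):
        with pytest.raises(ValueError, match="increasing"):
            category_probabilities(0.0, 1.0, [1.0, 0.0, -1.0, 2.0])


class TestGenerateResponses:
    def test_shape_and_dtype(self, small_study_data):
        data, bank, _ = small_study_data
        assert data.responses.shape == (250, 16)
        assert data.responses.min() >= 0 and data.responses.max() <= 4

    def test_dif_lowers_focal_scores_at_matched_theta(self):
        """At theta = 0, a focal threshold shift of 0.8 lowers expected score."""
        rng = np.random.default_rng(12)
        bank = sample_item_bank(16, rng=rng, dif_magnitude=0.8)
        n_cl, m = 100, 10
        ab = AbilitySample(
            theta=np.zeros(n_cl * m),
            cluster_id=np.repeat(np.arange(n_cl), m),
            cluster_effect=np.zeros(n_cl),
            icc=0.0,
        )
        groups = assign_groups(n_cl, m, "within", rng=rng)
        data = generate_responses(ab, bank, groups, "within", rng=rng)
        item = bank.studied_item
        mean_focal = data.responses[data.group == 1, item].mean()
        mean_ref = data.responses[data.group == 0, item].mean()
        # oracle expected scores at theta=0
        e_ref = float(np.arange(5) @ grm_category_probs(
            0.0, bank.discrimination[item], bank.thresholds[item]))
        e_foc = float(np.arange(5) @ grm_category_probs(
            0.0, bank.discrimination[item], bank.thresholds[item], 0.8))
        assert e_foc < e_ref
        assert mean_focal < mean_ref
        assert abs(mean_ref - e_ref) < 0.2 and abs(mean_focal - e_foc) < 0.2

    def test_null_dif_studied_item_exchangeable(self):
        rng = np.random.default_rng(14)
        data, bank, _ = simulate_dataset(100, 10, 0.05, 0.0, "within", rng=rng)
        item = bank.studied_item
        mf = data.responses[data.group == 1, item].mean()
        mr = data.responses[data.group == 0, item].mean()
        assert abs(mf - mr) < 0.2

    def test_marginal_frequencies_match_quadrature(self):
        """Simulated category frequencies converge to theta-integrated GRM."""
        rng = np.random.default_rng(15)
        a, b = 0.8, np.array([-1.2, -0.3, 0.6, 1.7])
        n = 50_000
        theta = rng.normal(size=n)
        tails = logistic(a * (theta[:, None] - b))
        y = (rng.random((n, 1)) < tails).sum(axis=1)
        # Gauss-Hermite integration of the GRM category probabilities
        x, w = np.polynomial.hermite.hermgauss(61)
        nodes = np.sqrt(2) * x
        probs = np.zeros(5)
        for k in range(5):
            pk = np.array([grm_category_probs(t, a, b)[k] for t in nodes])
            probs[k] = np.sum(w / np.sqrt(np.pi) * pk)
        freq = np.bincount(y, minlength=5) / n
        se = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(freq - probs) < 3 * se + 1e-12)

    def test_between_level_dif_follows_cluster_label(self):
        rng = np.random.default_rng(16)
        data, bank, _ = simulate_dataset(50, 4, 0.05, 0.8, "between", rng=rng)
        by_cluster = data.group.reshape(50, 4)
        assert np.all(by_cluster.std(axis=1) == 0)

    def test_reproducible_under_seed(self):
        d1, _, _ = simulate_dataset(20, 4, 0.25, 0.4, "within",
                                    rng=np.random.default_rng(17))
        d2, _, _ = simulate_dataset(20, 4, 0.25, 0.4, "within",
                                    rng=np.random.default_rng(17))
        np.testing.assert_array_equal(d1.responses, d2.responses)
        np.testing.assert_array_equal(d1.group, d2.group)
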