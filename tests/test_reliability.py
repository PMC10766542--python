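"""Connectivity matrices and test-retest reliability statistics."""

import numpy as np
import pytest
from scipy.special import comb

from reallife import Connectome
from reallife.reliability import (
    between_variability,
    connectivity_matrix,
    feature_index_map,
    feature_vector,
    reliability_summary,
    simulate_retest_cohort,
    top_percentile_filter,
    within_variability,
)


def _two_node(a, b):
    return np.array([[float(a), 0, 0], [float(b), 1, 0]])


class TestConnectivityMatrix:
    def test_counts_and_weights_accumulate(self):
        c = Connectome(
            [_two_node(0, 1), _two_node(2, 3)],
            labels=np.array([[1, 2], [1, 2]]),
        )
        m_count = connectivity_matrix(c, "count", r_per_hemisphere=4)
        m_weight = connectivity_matrix(
            c, np.array([0.3, 0.7]), r_per_hemisphere=4
        )
        assert m_count.left[0, 1] == m_count.left[1, 0] == 2
        assert m_weight.left[0, 1] == pytest.approx(1.0)
        assert np.all(m_count.right == 0)

    def test_self_connection_stays_on_diagonal(self):
        c = Connectome([_two_node(0, 1)], labels=np.array([[4, 4]]))
        m = connectivity_matrix(c, "count", r_per_hemisphere=4)
        assert m.left[3, 3] == 1
        assert m.left.sum() == 1

    def test_interhemispheric_excluded_and_counted(self):
        c = Connectome(
            [_two_node(0, 1), _two_node(2, 3)],
            labels=np.array([[1, 5], [2, 3]]),  # regions 5..8 = right hemi
        )
        m = connectivity_matrix(c, "count", r_per_hemisphere=4)
        assert m.n_interhemispheric == 1
        assert m.left[1, 2] == 1

    def test_empty_connectome_gives_zero_matrices(self):
        m = connectivity_matrix(
            Connectome([], labels=np.zeros((0, 2), dtype=int)),
            "count",
            r_per_hemisphere=3,
        )
        assert np.all(m.left == 0) and np.all(m.right == 0)

    def test_label_out_of_range_rejected(self):
        c = Connectome([_two_node(0, 1)], labels=np.array([[1, 9]]))
        with pytest.raises(ValueError, match="out of range"):
            connectivity_matrix(c, "count", r_per_hemisphere=4)


class TestFeatureVector:
    def _matrix(self, R, seed=0):
        rng = np.random.default_rng(seed)
        left = rng.uniform(size=(R, R))
        right = rng.uniform(size=(R, R))
        from reallife.reliability import ConnectivityMatrix

        return ConnectivityMatrix(left + left.T, right + right.T)

    def test_full_parcellation_length(self):
        assert feature_vector(self._matrix(34)).size == 1122

    def test_small_parcellation_length(self):
        assert feature_vector(self._matrix(3)).size == 6

    def test_index_map_round_trip(self):
        m = self._matrix(5, seed=3)
        vec = feature_vector(m)
        mapping = feature_index_map(5)
        assert len(mapping) == vec.size
        for k, (hemi, i, j) in enumerate(mapping):
            source = m.left if hemi == 0 else m.right
            assert vec[k] == source[i, j]
            assert i < j  # off-diagonal upper triangle only


class TestTopPercentileFilter:
    def test_full_feature_set_retains_half(self):
        rng = np.random.default_rng(0)
        values = rng.permutation(1122).astype(float)  # distinct
        kept = top_percentile_filter(values)
        assert kept.size == 561
        assert values[kept].min() > np.median(values) - 1

    def test_small_example(self):
        kept = top_percentile_filter(np.array([1.0, 2.0, 3.0, 4.0]))
        assert np.array_equal(kept, [2, 3])

    def test_ties_break_toward_lower_index(self):
        kept = top_percentile_filter(np.ones(6))
        assert np.array_equal(kept, [0, 1, 2])


class TestWithinVariability:
    def test_hand_arithmetic(self):
        vw, excl = within_variability([[2.0]], [[1.0]])
        assert vw[0] == pytest.approx(1.0 / 3.0)
        assert excl[0] == 0

    def test_perfect_retest_gives_zero(self):
        c = np.random.default_rng(0).uniform(1, 5, (4, 6))
        vw, _ = within_variability(c, c)
        assert np.all(vw == 0.0)

    def test_total_loss_gives_one(self):
        vw, _ = within_variability([[3.0]], [[0.0]])
        assert vw[0] == 1.0

    def test_both_zero_pairs_excluded(self):
        c1 = np.array([[0.0, 2.0], [4.0, 2.0]])
        c2 = np.array([[0.0, 1.0], [2.0, 2.0]])
        vw, excl = within_variability(c1, c2)
        assert np.isnan(vw[0]) or excl[0] == 1  # connection 0: one undefined pair
        assert excl[0] == 1 and vw[0] == pytest.approx(1.0 / 3.0)
        assert vw[1] == pytest.approx((1.0 / 3.0 + 0.0) / 2)


class TestBetweenVariability:
    def test_single_defined_ordered_pair(self):
        # participants l=0 (visit1 = 2) and m=1 (visit2 = 1): only the (0, 1)
        # ordered pair is defined; (1, 0) pairs 0 with 0 and is excluded
        c1 = np.array([[2.0], [0.0]])
        c2 = np.array([[0.0], [1.0]])
        vb, excl = between_variability(c1, c2)
        assert vb[0] == pytest.approx(1.0 / 3.0)
        assert excl[0] == 1

    def test_identical_cohort_gives_zero(self):
        c = np.full((3, 4), 2.5)
        vb, _ = between_variability(c, c)
        assert np.all(vb == 0.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        c1 = rng.uniform(0, 3, (5, 8))
        c2 = rng.uniform(0, 3, (5, 8))
        c1[c1 < 0.5] = 0.0
        c2[c2 < 0.5] = 0.0
        vb, excl = between_variability(c1, c2)
        for i in range(8):
            vals = []
            n_undef = 0
            for l in range(5):
                for m in range(5):
                    if l == m:
                        continue
                    denom = c1[l, i] + c2[m, i]
                    if denom > 0:
                        vals.append(abs(c1[l, i] - c2[m, i]) / denom)
                    else:
                        n_undef += 1
            assert vb[i] == pytest.approx(np.mean(vals), abs=1e-12)
            assert excl[i] == n_undef

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError, match="2 participants"):
            between_variability([[1.0]], [[1.0]])


class TestReliabilitySummary:
    def test_phi_known_values(self):
        out = reliability_summary(
            np.array([1.0, 2.0, 0.0]), np.array([1.0, 0.0, 3.0])
        )
        assert out.phi[0] == pytest.approx(0.5)  # V_b = V_w
        assert out.phi[1] == 1.0  # V_w = 0
        assert out.phi[2] == 0.0  # V_b = 0

    def test_binomial_tail_closed_form(self):
        # 13 high vs 8 low: one-sided tail sum_{k>=13} C(21,k) / 2^21
        rng = np.random.default_rng(1)
        n_high, n_low = 13, 8
        dvb = np.concatenate([np.ones(n_high), -np.ones(n_low)]) * rng.uniform(
            0.1, 1, n_high + n_low
        )
        dvw = -dvb
        vb_u = np.full(21, 0.5)
        vw_u = np.full(21, 0.5)
        out = reliability_summary(vb_u + dvb * 0.1, vw_u + dvw * 0.1, vb_u, vw_u)
        assert out.n_high == n_high and out.n_low == n_low
        expect = sum(comb(21, k, exact=True) for k in range(13, 22)) / 2**21
        assert out.p_binomial == pytest.approx(expect, rel=1e-12)

    def test_boundary_connections_fall_in_neither_quadrant(self):
        vb = np.array([0.5, 0.6])
        vw = np.array([0.5, 0.4])
        out = reliability_summary(vb, vw, vb, vw)  # delta = 0 everywhere
        assert list(out.quadrant) == ["neither", "neither"]

    def test_scale_invariance_of_variability_and_phi(self):
        rng = np.random.default_rng(3)
        c1 = rng.uniform(0.5, 3, (4, 6))
        c2 = rng.uniform(0.5, 3, (4, 6))
        for scale in (1.0, 7.3):
            vw, _ = within_variability(scale * c1, scale * c2)
            vb, _ = between_variability(scale * c1, scale * c2)
            if scale == 1.0:
                ref = reliability_summary(vb, vw).phi
            else:
                assert np.allclose(reliability_summary(vb, vw).phi, ref)


class TestDirectionRecovery:
    def test_between_spread_dominates_gives_high_phi(self):
        phis = []
        for seed in range(3):
            c1, c2 = simulate_retest_cohort(
                n_participants=6, n_connections=40,
                between_sd=0.8, within_sd=0.02, seed=seed,
            )
            vw, _ = within_variability(c1, c2)
            vb, _ = between_variability(c1, c2)
            phis.append(reliability_summary(vb, vw).mean_phi)
        assert np.mean(phis) > 0.5

    def test_within_noise_dominates_gives_low_phi(self):
        phis = []
        for seed in range(3):
            c1, c2 = simulate_retest_cohort(
                n_participants=6, n_connections=40,
                between_sd=0.02, within_sd=0.8, seed=seed,
            )
            vw, _ = within_variability(c1, c2)
            vb, _ = between_variability(c1, c2)
            phis.append(reliability_summary(vb, vw).mean_phi)
        assert np.mean(phis) < 0.5

    def test_noiseless_visits_give_phi_exactly_one(self):
        c1, c2 = simulate_retest_cohort(
            n_participants=4, n_connections=20,
            between_sd=0.5, within_sd=0.0, seed=1,
        )
        vw, _ = within_variability(c1, c2)
        vb, _ = between_variability(c1, c2)
        phi = reliability_summary(vb, vw).phi
        assert np.all(vw == 0.0)
        assert np.all(phi == 1.0)
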