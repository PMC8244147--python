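"""Unit and property tests for the closed-form accuracy algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gpacc.accuracy_core as ac


GRID_R2 = [0.01, 0.1, 0.3, 0.5, 0.7, 0.95]
GRID_Q2 = [0.5, 0.8, 1.0]
GRID_H2 = [0.1, 0.4, 0.9]


class TestQ2FromMe:
    @pytest.mark.parametrize(
        "M, Me, expected",
        [
            (10_000, 0, 1.0),
            (5_000, 5_000, 0.5),
            (23_356, 3_727, 0.8624),
        ],
    )
    def test_values(self, M, Me, expected):
        assert ac.q2_from_me(M, Me) == pytest.approx(expected, abs=5e-5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ac.q2_from_me(-1, 100)
        with pytest.raises(ValueError):
            ac.q2_from_me(100, -1)


class TestThetaR2Conversions:
    def test_zero_accuracy_gives_zero_information(self):
        assert ac.theta_from_r2(0.0, 1.0, 0.4) == 0.0
        assert ac.r2_from_theta(0.0, 1.0, 0.4) == 0.0

    def test_real_data_value(self):
        # theta of the DEBV accuracy observed in the layer-chicken reference
        theta = ac.theta_from_r2(0.277**2, 1.0, 0.523)
        assert theta == pytest.approx(0.07977, abs=5e-6)
        assert ac.r2_from_theta(theta, 1.0, 0.523) == pytest.approx(
            0.277**2, abs=1e-10
        )

    def test_divergence_near_bound(self):
        assert ac.theta_from_r2(0.9999, 1.0, 0.4) > 1e3
        with pytest.raises(ValueError):
            ac.theta_from_r2(1.0, 1.0, 0.4)

    def test_asymptotic_limit_is_q2(self):
        assert ac.r2_from_theta(1e6, 0.8, 0.4) == pytest.approx(0.8, abs=1e-4)

    @pytest.mark.parametrize("q2", GRID_Q2)
    @pytest.mark.parametrize("h2", GRID_H2)
    def test_roundtrip_grid(self, q2, h2):
        for frac in GRID_R2:
            r2 = frac * q2
            theta = ac.theta_from_r2(r2, q2, h2)
            assert ac.r2_from_theta(theta, q2, h2) == pytest.approx(r2, abs=1e-10)

    @pytest.mark.parametrize("q2,h2", [(1.0, 0.4), (0.8, 0.2)])
    def test_monotone_in_r2(self, q2, h2):
        r2s = np.linspace(0.0, 0.95 * q2, 40)
        thetas = [ac.theta_from_r2(r2, q2, h2) for r2 in r2s]
        assert np.all(np.diff(thetas) > 0)


class TestFisherAdditivity:
    def test_identity_and_sum(self):
        assert ac.fisher_combine(0.0, 0.7) == 0.7
        assert ac.fisher_combine(0.3, 0.5) == pytest.approx(0.8)
        assert ac.fisher_extract(ac.fisher_combine(0.3, 0.5), 0.3) == pytest.approx(
            0.5
        )

    def test_combined_accuracy_dominates_components(self):
        h2 = 0.4
        tA = ac.theta_from_r2(0.25, 1.0, h2)
        tD = ac.theta_from_r2(0.16, 1.0, h2)
        rG2 = ac.r2_from_theta(ac.fisher_combine(tA, tD), 1.0, h2)
        assert rG2 >= 0.25

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ac.fisher_combine(-0.1, 0.5)


class TestIndexCombination:
    @pytest.mark.parametrize(
        "rA2, rD2, expected",
        [
            (0.25, 0.0, 0.25),
            (1.0, 0.3, 1.0),
            (0.25, 0.25, 0.4),
        ],
    )
    def test_values(self, rA2, rD2, expected):
        assert ac.index_combine_r2(rA2, rD2) == pytest.approx(expected)

    def test_extract_is_inverse(self):
        for a in [0.0, 0.1, 0.3, 0.6, 0.9]:
            for d in [0.0, 0.1, 0.3, 0.6, 0.9]:
                g = ac.index_combine_r2(a, d)
                assert ac.index_extract_rD2(g, a) == pytest.approx(d, abs=1e-12)

    def test_extract_degenerate_clamps_with_warning(self):
        assert ac.index_extract_rD2(0.3, 0.3) == 0.0
        with pytest.warns(UserWarning):
            assert ac.index_extract_rD2(0.2, 0.25) == 0.0
        with pytest.raises(ValueError):
            ac.index_extract_rD2(0.2, 0.25, policy="strict")

    def test_dominance_gap_closed_form(self):
        # r_G^2 - r_A^2 equals r_D^2 (1 - r_A^2)^2 / (1 - r_A^2 r_D^2)
        for a in [0.0, 0.2, 0.5, 0.8]:
            for d in [0.0, 0.2, 0.5, 0.8]:
                gap = ac.index_combine_r2(a, d) - a
                assert gap == pytest.approx(
                    d * (1 - a) ** 2 / (1 - a * d), abs=1e-12
                )
                assert ac.index_combine_r2(a, d) >= max(a, d) - 1e-12


@settings(deadline=None, max_examples=200)
@given(
    a=st.floats(0.0, 0.99),
    d=st.floats(0.0, 0.99),
)
def test_index_combine_symmetric_and_dominant(a, d):
    g1 = ac.index_combine_r2(a, d)
    g2 = ac.index_combine_r2(d, a)
    assert g1 == pytest.approx(g2, abs=1e-12)
    assert g1 >= max(a, d) - 1e-12
    assert g1 <= 1.0 + 1e-12


class TestMeEstimators:
    def test_fisher_quadratic_root(self):
        me = ac.me_fisher_from_theta_d(0.5, 0.4, 1_000, 10_000)
        assert me == pytest.approx(744.56, abs=0.01)
        # residual of the defining quadratic
        resid = 0.5 * me**2 + 0.5 * 10_000 * me - 1_000 * 10_000 * 0.4
        assert abs(resid) / (1_000 * 10_000 * 0.4) < 1e-8

    def test_fisher_recovers_known_me(self):
        # construct theta_D from a known Me and recover it
        Me0, M, N, h2 = 1_000.0, 50_000.0, 2_000.0, 0.4
        theta_D = N * h2 / Me0 * M / (M + Me0)
        assert ac.me_fisher_from_theta_d(theta_D, h2, N, M) == pytest.approx(
            Me0, rel=1e-10
        )

    def test_fisher_infinite_information_limit(self):
        assert ac.me_fisher_from_theta_d(1e9, 0.4, 1_000, 10_000) < 1e-2

    def test_fisher_requires_genomic_gain(self):
        with pytest.raises(ValueError):
            ac.me_fisher(0.4, 0.5, 0.4, 1_000, 10_000)

    def test_index_real_data(self):
        # the layer-chicken reference: r_D = 0.277, h2 = 0.523, N = 777
        me, q2 = ac.me_index(0.277, 0.523, 777, 23_356)
        assert me == pytest.approx(3_727, rel=0.01)
        assert q2 == pytest.approx(23_356 / (23_356 + me), rel=1e-10)

    def test_index_closed_form_with_dense_panel(self):
        me, q2 = ac.me_index(math.sqrt(0.1), 0.4, 1_000, 10**9, fixed_q2=1.0)
        assert me == pytest.approx(3_750, rel=1e-10)
        assert q2 == 1.0

    def test_index_diverges_for_vanishing_signal(self):
        me_small, _ = ac.me_index(1e-3, 0.4, 1_000, 10_000)
        me_tiny, _ = ac.me_index(1e-4, 0.4, 1_000, 10_000)
        assert me_tiny > me_small > 1e4

    def test_index_fixed_point_residual(self):
        me, q2 = ac.me_index(0.35, 0.3, 800, 5_000)
        theta_D = ac.theta_from_r2(0.35**2, q2, 0.3)
        assert me == pytest.approx(800 * q2 * 0.3 / theta_D, rel=1e-7)

    @pytest.mark.parametrize("route", ["fisher", "index"])
    def test_both_decrease_in_r_G(self, route):
        h2, N, M, rA = 0.4, 1_000, 10_000, 0.4
        mes = []
        for rG in [0.45, 0.55, 0.65, 0.75]:
            if route == "fisher":
                mes.append(ac.me_fisher(rG, rA, h2, N, M))
            else:
                rD2 = ac.index_extract_rD2(rG**2, rA**2)
                mes.append(ac.me_index(math.sqrt(rD2), h2, N, M)[0])
        assert np.all(np.diff(mes) < 0)


class TestMeTheoretical:
    @pytest.mark.parametrize(
        "Ne, variant, expected",
        [
            (37, "plain", 999.0),
            (37, "log_corrected", 248.74),
            (120, "plain", 3_240.0),
        ],
    )
    def test_values(self, Ne, variant, expected):
        assert ac.me_theoretical(Ne, 1.5, 9, variant) == pytest.approx(
            expected, abs=0.01
        )

    def test_log_correction_domain(self):
        with pytest.raises(ValueError):
            ac.me_theoretical(0.5, 1.0, 9, "log_corrected")


class TestErosion:
    def test_inside_reference_no_loss(self):
        assert ac.p_rt(100, 9, 1.5, 2.0, ac.DistanceToReference(0, 0)) == 1.0

    def test_real_data_per_generation_factor(self):
        p = ac.p_rt(3_705, 9, 30 / 9, 2.0, ac.DistanceToReference(1, 1))
        assert p == pytest.approx(0.9679, abs=5e-5)

    def test_boundary_clamp(self):
        with pytest.warns(UserWarning):
            assert ac.p_rt(27, 9, 1.5, 2.0, ac.DistanceToReference(1, 1)) == 0.0

    def test_multiplicative_over_generations(self):
        for (a, b), (c, d) in [((1, 1), (1, 2)), ((0, 2), (3, 0))]:
            p_joint = ac.p_rt(500, 9, 1.5, 2.0, ac.DistanceToReference(a + c, b + d))
            p_split = ac.p_rt(500, 9, 1.5, 2.0, ac.DistanceToReference(a, b)) * ac.p_rt(
                500, 9, 1.5, 2.0, ac.DistanceToReference(c, d)
            )
            assert p_joint == pytest.approx(p_split, rel=1e-12)

    def test_monotonicity(self):
        dist = ac.DistanceToReference(1, 1)
        p_near = ac.p_rt(1_000, 9, 1.5, 2.0, dist)
        p_far = ac.p_rt(1_000, 9, 1.5, 2.0, ac.DistanceToReference(2, 2))
        assert p_far < p_near
        assert ac.p_rt(2_000, 9, 1.5, 2.0, dist) > p_near


class TestTargetPrediction:
    def test_pure_genomic_carryover(self):
        ctx = ac.PredictionContext(h2=0.4, N=1_000, M=10_000, Me=1_000)
        res = ac.predict_target_accuracy(
            0.5, 0.0, ctx, ac.DistanceToReference(0, 0), combine="index"
        )
        assert res.r_G == pytest.approx(0.5, abs=1e-12)

    def test_pedigree_only(self):
        ctx = ac.PredictionContext(h2=0.4, N=1_000, M=10_000, Me=1_000)
        res = ac.predict_target_accuracy(
            0.0, 0.6, ctx, ac.DistanceToReference(3, 3), combine="index"
        )
        assert res.r_G == pytest.approx(0.6, abs=1e-12)

    def test_composition_of_erosion_and_index(self):
        # one generation of erosion at the real-data Me, then index combination
        ctx = ac.PredictionContext(
            h2=0.523, N=777, M=23_356, Me=3_705, k=9, L=30 / 9, gamma=2.0
        )
        res = ac.predict_target_accuracy(
            0.5, 0.5, ctx, ac.DistanceToReference(1, 1), combine="index"
        )
        assert res.r_D == pytest.approx(0.48394, abs=5e-5)
        assert res.r_G == pytest.approx(0.62444, abs=5e-5)

    def test_target_never_below_pedigree(self):
        ctx = ac.PredictionContext(h2=0.4, N=500, M=2_000, Me=800)
        for route in ("fisher", "index"):
            res = ac.predict_target_accuracy(
                0.4, 0.45, ctx, ac.DistanceToReference(2, 2), combine=route
            )
            assert res.r_G >= 0.45 - 1e-12


class TestSelectionAdjustment:
    def test_no_bulmer_effect(self):
        vs = ac.VarianceState(1.0, 1.0)
        assert ac.selection_adjusted_r2(0.5, vs) == pytest.approx(0.5)

    def test_reduced_variance_raises_accuracy(self):
        vs = ac.VarianceState(1.0, 0.8)
        assert ac.selection_adjusted_r2(0.5, vs) == pytest.approx(0.6)

    def test_limit_and_inconsistency(self):
        vs = ac.VarianceState(1.0, 1e-9)
        assert ac.selection_adjusted_r2(0.9, vs) == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(ValueError):
            ac.selection_adjusted_r2(0.1, ac.VarianceState(1.0, 2.0))


class TestContextValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"h2": 0.0},
            {"h2": 1.5},
            {"Me": -5.0},
            {"q2": 0.0},
            {"gamma": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(h2=0.4, N=1_000, M=10_000, Me=1_000)
        base.update(kwargs)
        with pytest.raises(ValueError):
            ac.PredictionContext(**base)

    def test_distance_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            ac.DistanceToReference(-1, 0)
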