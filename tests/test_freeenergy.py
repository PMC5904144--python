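"""Positional free-energy model: term forms, linearity, partition-sum oracles."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from knotfactory.freeenergy import (
    FreeEnergyParams,
    CompressionState,
    piston_state,
    f_bulk,
    f_wall_knot,
    f_wall_unknot,
    f1,
    f1_decomposition,
    z_single,
    z_multi,
    Z_state,
    predict_probabilities,
    predict_position_distributions,
    KnotProbabilityTable,
    KnotFreeEnergyModel,
)

from oracles import z_multi_oracle

PARAMS = FreeEnergyParams()


class TestTerms:
    def test_bulk_inverse_contour(self):
        assert f_bulk(1e9, PARAMS) < 1e-6
        L_unit = PARAMS.b_bend * PARAMS.P_um
        assert f_bulk(L_unit, PARAMS) == pytest.approx(1.0)
        assert f_bulk(1.0, PARAMS) == pytest.approx(2 * f_bulk(2.0, PARAMS))

    def test_bulk_domain_error(self):
        with pytest.raises(ValueError):
            f_bulk(0.0, PARAMS)

    def test_wall_gated_and_continuous(self):
        gate = PARAMS.chi * PARAMS.channel.D_av_um
        assert f_wall_knot(0.5 * gate, PARAMS) == 0.0
        assert f_wall_knot(gate * (1 - 1e-9), PARAMS) == 0.0
        assert f_wall_knot(gate * (1 + 1e-9), PARAMS) == pytest.approx(0.0, abs=1e-6)
        # cubic growth: (2^3 - 1) kappa_wall at twice the gate
        assert f_wall_knot(2 * gate, PARAMS) == pytest.approx(7 * PARAMS.kappa_wall)

    def test_self_exclusion_saving_linear(self):
        st_ = piston_state(0.125)
        base = f_wall_unknot(2.0, 0.0, st_, PARAMS)
        assert base == pytest.approx(PARAMS.kappa_excl * st_.C_b * 2.0)
        assert f_wall_unknot(4.0, 0.0, st_, PARAMS) == pytest.approx(2 * base)
        eq = CompressionState(R_b=1.0, R_c=1.0, alpha=0.0)
        assert f_wall_unknot(2.0, 0.5, eq, PARAMS) == pytest.approx(
            PARAMS.kappa_excl * 2.0)

    def test_exclusion_domain_error(self):
        st_ = piston_state(0.125)
        with pytest.raises(ValueError):
            f_wall_unknot(2.0, st_.R_c + 0.1, st_, PARAMS)


class TestF1Linearity:
    def test_all_terms_off_gives_zero(self):
        pr = replace(PARAMS, A_b=1e-12, A_wk=1e-12, A_h=1e-12, kappa_excl=1e-12)
        st_ = piston_state(0.2)
        val = f1(3.0, 0.1, st_, pr)
        assert abs(val) < 1e-9

    @given(st.floats(0.5, 12.0), st.floats(0.0, 1.0), st.floats(0.09, 0.9))
    @settings(max_examples=150, deadline=None)
    def test_decomposition_matches_direct_form(self, L_k, frac, R_b):
        """f1(X) = f1(0) + beta X holds identically for arbitrary inputs."""
        st_ = piston_state(R_b)
        X = frac * st_.R_c
        base, beta = f1_decomposition(L_k, st_, PARAMS)
        direct = f1(L_k, X, st_, PARAMS)
        assert direct == pytest.approx(float(base) + float(beta) * X,
                                       rel=1e-12, abs=1e-12)

    def test_beta_matches_finite_difference(self):
        st_ = piston_state(0.15)
        _, beta = f1_decomposition(3.0, st_, PARAMS)
        h = 1e-6
        fd = (f1(3.0, 2 * h, st_, PARAMS) - f1(3.0, h, st_, PARAMS)) / h
        assert float(beta) == pytest.approx(float(fd), rel=1e-5)

    def test_barrier_free_energy_negative_at_strong_compression(self):
        grid = np.geomspace(*PARAMS.L_k_range, 400)
        base, _ = f1_decomposition(grid, piston_state(0.085), PARAMS)
        assert base.min() < 0.0


class TestPartitionSums:
    def test_site_count_floor(self):
        # r = 1.43 um with g_k = 100 nm -> floor(1430/200) = 7 sites
        pr = replace(PARAMS, chi=12.0)
        st_ = CompressionState(R_b=0.0667, R_c=0.1, alpha=0.0, r_o=14.3)
        L = 1.2  # g_k = 0.1 um
        w = 2 * pr.g_k(L) / st_.r_o
        assert int(np.floor(st_.R_c / w)) == 7

    def test_flat_landscape_counts_sites(self):
        pr = replace(PARAMS, A_b=1e-9, A_wk=1e-9, A_h=1e-9, kappa_excl=1e-9)
        st_ = CompressionState(R_b=0.5, R_c=0.5, alpha=0.0)
        L = 1.2
        w = 2 * pr.g_k(L) / st_.r_o
        n_max = int(np.floor(st_.R_c / w))
        assert z_single(L, st_, pr) == pytest.approx(n_max, rel=1e-6)

    def test_single_site_fallback_for_oversized_knot(self):
        st_ = CompressionState(R_b=0.1, R_c=0.1, alpha=0.0)
        L_big = 12.0  # 2 g_k = 2 um > r = 1.43 um
        assert z_single(L_big, st_, PARAMS) > 0.0

    def test_geometric_form_equals_site_summation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            st_ = piston_state(float(rng.uniform(0.09, 0.6)))
            L = float(rng.uniform(0.8, 10.0))
            base, beta = f1_decomposition(L, st_, PARAMS)
            w = 2 * PARAMS.g_k(L) / st_.r_o
            n_max = max(int(np.floor(st_.R_c / w + 1e-12)), 1)
            brute = sum(np.exp(-(float(base) + float(beta) * i * w))
                        for i in range(n_max))
            assert z_single(L, st_, PARAMS) == pytest.approx(brute, rel=1e-12)

    def test_ordered_placements_count(self):
        """Three identical sites, two identical knots, flat landscape:
        C(3,2) = 3 ordered placements."""
        pr = replace(PARAMS, A_b=1e-12, A_wk=1e-12, A_h=1e-12, kappa_excl=1e-12,
                     chi=12.0)
        L = 1.2
        st_ = CompressionState(R_b=0.3, R_c=3 * 2 * pr.g_k(L) / 14.3, alpha=0.0)
        assert z_multi([L, L], st_, pr) == pytest.approx(3.0, rel=1e-9)

    def test_single_file_ground_state_at_high_compression(self):
        """When the chain just fits the knots there is exactly one
        configuration: knots stacked against the barrier."""
        L1, L2 = 2.0, 3.0
        w1 = 2 * PARAMS.g_k(L1) / 14.3
        w2 = 2 * PARAMS.g_k(L2) / 14.3
        st_ = CompressionState(R_b=0.2, R_c=(w1 + w2) * 1.0001, alpha=0.0)
        expected = np.exp(-float(f1(L1, 0.0, st_, PARAMS))
                          - float(f1(L2, w1, st_, PARAMS)))
        assert z_multi([L1, L2], st_, PARAMS) == pytest.approx(expected, rel=1e-9)

    def test_overfull_chain_has_zero_states(self):
        st_ = CompressionState(R_b=0.1, R_c=0.05, alpha=0.0)
        assert z_multi([10.0, 10.0], st_, PARAMS) == 0.0

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_recursion_equals_enumeration_oracle(self, m):
        """100 random instances with n_max <= 8 per knot, checked against
        explicit enumeration of all ordered placements."""
        rng = np.random.default_rng(10 + m)
        checked = 0
        while checked < 100 // m + 10:
            pr = replace(
                PARAMS,
                b_bend=float(rng.uniform(50, 400)),
                kappa_excl=float(rng.uniform(0.05, 0.5)),
                kappa_wall=float(rng.uniform(0.2, 3.0)),
                zeta_per_alpha=float(rng.uniform(0.0, 1.0)),
            )
            st_ = piston_state(float(rng.uniform(0.1, 0.5)))
            L = rng.uniform(2.0, 8.0, size=m)
            w = 2 * pr.g_k(L) / st_.r_o
            if st_.R_c / w.min() > 8 or st_.R_c < w.sum():
                continue
            got = z_multi(L, st_, pr)
            want = z_multi_oracle(L, st_, pr)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-300)
            checked += 1


class TestZState:
    def test_zero_knots_unity(self):
        assert Z_state(0, piston_state(0.2), PARAMS) == 1.0

    def test_quadrature_error_estimate_small(self):
        st_ = piston_state(0.12)
        val, err = Z_state(1, st_, PARAMS, return_error=True)
        assert err < 1e-3 * max(val, 1e-12)

    def test_poisson_factorization_when_independent(self):
        st_ = piston_state(0.85)
        Z1 = Z_state(1, st_, PARAMS, order=48)
        Z2 = Z_state(2, st_, PARAMS, exclusion=False, order=48)
        assert Z2 == pytest.approx(Z1**2 / 2.0, rel=2e-3)

    def test_laplace_oracle_for_peaked_integrand(self):
        """Saddle-point estimate of the contour integral agrees within 5%
        when the integrand is sharply peaked (smooth interior minimum)."""
        pr = replace(PARAMS, wall_C_coupling=False, b_bend=760.0,
                     kappa_wall=1.0, kappa_excl=0.17, chi=12.0,
                     zeta_per_alpha=0.3)
        st_ = piston_state(0.10)
        grid = np.geomspace(*pr.L_k_range, 4001)
        h = z_single(grid, st_, pr)
        i = int(np.argmax(h))
        logh = np.log(h[i - 1: i + 2])
        dL = np.log(grid[1] / grid[0])  # uniform in log L
        # curvature of log h in log L, transformed to linear L at the peak
        d2 = (logh[0] - 2 * logh[1] + logh[2]) / dL**2
        L_pk = grid[i]
        curv = -(d2 - 0.0) / L_pk**2  # d2/dL2 of -log h, leading order
        laplace = h[i] * np.sqrt(2 * np.pi / curv) / pr.two_P
        exact = Z_state(1, st_, pr, order=64)
        assert laplace == pytest.approx(exact, rel=0.05)


class TestPredictions:
    def test_probabilities_normalized(self):
        for rb in (0.09, 0.15, 0.4):
            tab = predict_probabilities(piston_state(rb), PARAMS, n_k=3)
            assert tab["P"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_free_energy_identities(self):
        tab = predict_probabilities(piston_state(0.12), PARAMS, n_k=2)
        Z = tab["Z"].to_numpy()
        F = tab["F_tot"].to_numpy()
        assert F[1] == pytest.approx(-np.log(Z[1]), rel=1e-12)
        assert tab.attrs["F2_int"] == pytest.approx(
            F[2] - 2 * F[1] - np.log(2.0), abs=1e-12)

    def test_interaction_free_energy_nonnegative_under_exclusion(self):
        """Pure no-passing width exclusion can only remove configurations,
        so F2_int >= 0 (beta >= 0 throughout with these parameter signs)."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            pr = replace(PARAMS, wall_C_coupling=False,
                         b_bend=float(rng.uniform(300, 900)),
                         kappa_excl=float(rng.uniform(0.1, 0.4)),
                         zeta_per_alpha=float(rng.uniform(0.0, 1.0)))
            st_ = piston_state(float(rng.uniform(0.09, 0.5)))
            Z1 = Z_state(1, st_, pr, order=32)
            Z2 = Z_state(2, st_, pr, order=24)
            F2_int = -np.log(Z2) + 2 * np.log(Z1) + np.log(2.0)
            assert F2_int >= -1e-6

    def test_total_knotting_monotone_in_compression(self):
        rbs = [0.09, 0.11, 0.13, 0.17, 0.25, 0.4]
        totals = [1 - predict_probabilities(piston_state(rb), PARAMS,
                                            n_k=2)["P"].iloc[0]
                  for rb in rbs]
        assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:]))

    def test_three_knot_states_strongly_suppressed(self):
        for rb in (0.09, 0.12, 0.2):
            tab = predict_probabilities(piston_state(rb), PARAMS, n_k=3)
            P = tab["P"].to_numpy()
            assert P[3] < 0.15 * max(P[2], 1e-12) or P[3] < 1e-4


class TestPositionDistributions:
    def test_flat_slope_uniform_over_sites(self):
        pr = replace(PARAMS, zeta_per_alpha=0.0, kappa_excl=1e-12, A_h=1e-12)
        st_ = CompressionState(R_b=0.3, R_c=0.3, alpha=0.0)
        X, p = predict_position_distributions(st_, pr, m=1, L_k=[2.0])
        assert np.allclose(p, p[0])

    def test_upper_knot_excluded_near_barrier(self):
        st_ = piston_state(0.12)
        lo_x, lo_p, up_x, up_p = predict_position_distributions(
            st_, PARAMS, m=2, L_k=[2.0, 2.0])
        w = 2 * PARAMS.g_k(2.0) / st_.r_o
        assert lo_x[0] == pytest.approx(0.0)
        assert up_x[0] == pytest.approx(w)  # gap where only one knot is found
        assert abs(lo_p.sum() - 1) < 1e-9 and abs(up_p.sum() - 1) < 1e-9

    def test_marginals_match_monte_carlo_oracle(self):
        st_ = piston_state(0.13)
        L = [2.5, 2.5]
        lo_x, lo_p, up_x, up_p = predict_position_distributions(
            st_, PARAMS, m=2, L_k=L)
        # independent MC: enumerate configurations via f1 directly, sample
        w = [2 * PARAMS.g_k(Lj) / st_.r_o for Lj in L]
        slack = st_.R_c - sum(w)
        configs, weights = [], []
        d1 = 0
        while d1 * w[0] <= slack + 1e-12:
            a1 = d1 * w[0]
            d2 = 0
            while a1 + w[0] + d2 * w[1] + w[1] <= st_.R_c + 1e-12:
                a2 = a1 + w[0] + d2 * w[1]
                configs.append((a1, a2))
                weights.append(np.exp(-float(f1(L[0], a1, st_, PARAMS))
                                      - float(f1(L[1], a2, st_, PARAMS))))
                d2 += 1
            d1 += 1
        weights = np.array(weights) / np.sum(weights)
        rng = np.random.default_rng(9)
        draws = rng.multinomial(100_000, weights)
        emp_lo = {}
        for (a1, a2), n in zip(configs, draws):
            emp_lo[a1] = emp_lo.get(a1, 0) + n
        for x, p in zip(lo_x, lo_p):
            n_emp = emp_lo.get(x, 0)
            sd = np.sqrt(100_000 * p * (1 - p))
            assert abs(n_emp - 100_000 * p) <= 3 * max(sd, 1.0)


class TestAFitGuards:
    def test_too_few_conditions_rejected(self):
        rows = []
        for rb in (0.1, 0.2):
            for m in range(3):
                rows.append({"R_b": rb, "m": m, "P": 0.3,
                             "wilson_lo": 0.2, "wilson_hi": 0.4})
        obs = KnotProbabilityTable(pd.DataFrame(rows), {})
        with pytest.raises(ValueError):
            KnotFreeEnergyModel(obs, PARAMS, mode="full")
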