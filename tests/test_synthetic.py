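"""Synthetic-data generators: conservation laws, determinism, ground truth."""

import numpy as np
import pytest

from knotfactory.synthetic import (
    TrueProfileSpec,
    KnotSpec,
    KymographSpec,
    InvalidSpecError,
    gen_equilibrium_profile,
    gen_compressed_profile,
    gen_piston_series,
    gen_event_counts,
    gen_kymograph,
    gen_knot_positions,
    sample_event_spec,
    solve_R_c,
)
from knotfactory.stats import trunc_exp_mean


class TestProfiles:
    def test_equilibrium_integral_conserved(self):
        spec = TrueProfileSpec(r_o=14.3, c_o=1.0, sigma_psf=0.3)
        prof = gen_equilibrium_profile(spec, 2048, 0)
        assert np.trapezoid(prof.intensity, prof.x) == pytest.approx(14.3, abs=1e-5)

    def test_equilibrium_sigma_to_zero_is_box(self):
        spec = TrueProfileSpec(sigma_psf=1e-9)
        prof = gen_equilibrium_profile(spec, 512, 0)
        inside = (prof.x > 0.1) & (prof.x < spec.r_o - 0.1)
        outside = (prof.x < -0.1) | (prof.x > spec.r_o + 0.1)
        assert np.allclose(prof.intensity[inside], spec.c_o)
        assert np.allclose(prof.intensity[outside], 0.0)

    def test_noise_mean_converges_to_clean(self):
        spec = TrueProfileSpec()
        clean = gen_equilibrium_profile(spec, 128, 0).intensity
        reps = np.stack([
            gen_equilibrium_profile(spec, 128, s, noise=(0.03, 0.08)).intensity
            for s in range(100)
        ])
        se = reps.std(axis=0, ddof=1) / np.sqrt(reps.shape[0])
        dev = np.abs(reps.mean(axis=0) - clean)
        assert np.max(dev - 3 * np.maximum(se, 1e-6)) < 0.0

    def test_compressed_integral_is_unit_area(self):
        spec = TrueProfileSpec.compressed(C_b=10.0, R_c=0.13)
        prof = gen_compressed_profile(spec, 4096, 0)
        # integral over X = x/r_o of C = I/c_o equals the ramp area = 1
        area = np.trapezoid(prof.intensity / spec.c_o, prof.x / spec.r_o)
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_compressed_invariant_violation_raises(self):
        bad = TrueProfileSpec(C_b=2.0, alpha=30.0, R_c=0.5)  # negative tail
        with pytest.raises(InvalidSpecError):
            gen_compressed_profile(bad, 256, 0)

    def test_solve_R_c_matches_stated_example(self):
        assert solve_R_c(10.0, 35.50295857988166) == pytest.approx(0.13, abs=1e-9)

    def test_deterministic_given_seed(self):
        spec = TrueProfileSpec()
        a = gen_equilibrium_profile(spec, 128, 7, noise=(0.03, 0.08))
        b = gen_equilibrium_profile(spec, 128, 7, noise=(0.03, 0.08))
        assert np.array_equal(a.intensity, b.intensity)


class TestPistonSeries:
    def test_generated_scalings_exact(self):
        series = gen_piston_series(1.5, 2.0, [1.0, 2.0, 4.0, 8.0])
        V = np.array([v for v, _ in series])
        C_b = np.array([s.C_b for _, s in series])
        alpha = np.array([s.alpha for _, s in series])
        slope = np.polyfit(np.log(V), np.log(C_b), 1)[0]
        assert slope == pytest.approx(0.5, abs=1e-10)
        # alpha * R_b^2 = a / b^2 is constant by construction
        R_b = 1.0 / C_b
        prod = alpha * R_b**2
        assert np.ptp(prod) / prod.mean() < 1e-6

    def test_zero_flow_rejected(self):
        with pytest.raises(ValueError):
            gen_piston_series(1.5, 2.0, [1.0, 0.0])


class TestEventCounts:
    def test_degenerate_multinomial(self):
        tab = gen_event_counts([(0.13, 5.0, 15)], [(1.0, 0.0, 0.0, 0.0)], seed=0)
        counts = tab.counts_at(0.13)
        assert counts[0] == 15 and counts[1:].sum() == 0

    def test_large_n_within_binomial_sd(self):
        n = 100_000
        tab = gen_event_counts([(0.1, 1.0, n)], [(0.25,) * 4], seed=1)
        counts = tab.counts_at(0.1)
        sd = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(counts - n / 4) < 5 * sd)

    def test_zero_events_no_error(self):
        tab = gen_event_counts([(0.1, 1.0, 0)], [(0.5, 0.5)], seed=0)
        assert tab.counts_at(0.1).sum() == 0

    def test_bad_probabilities_rejected(self):
        with pytest.raises(ValueError):
            gen_event_counts([(0.1, 1.0, 5)], [(0.5, 0.4)], seed=0)


class TestKymographs:
    def test_zero_knot_movie_matches_truth(self):
        spec = sample_event_spec(0, seed=3)
        ky = gen_kymograph(spec)
        assert ky.truth["m_true"] == 0
        assert ky.truth["knots"] == []
        assert ky.data.shape[0] == len(ky.times)

    def test_static_knots_have_constant_centroids_during_hold(self):
        prof = TrueProfileSpec.compressed(C_b=8.0, R_c=0.2)
        knots = [KnotSpec(7.0, 0.6, 1.5, diffusivity=0.0),
                 KnotSpec(7.0, 1.8, 2.0, diffusivity=0.0)]
        ky = gen_kymograph(KymographSpec(profile=prof, knots=knots, seed=0))
        hold = dict((n, b) for n, b in ky.truth["phases"])["hold"]
        for rec, want in zip(ky.truth["knots"], (0.6, 1.8)):
            tr = rec["track"]
            sel = [(hold[0] <= t < hold[1]) for t in tr["t"]]
            xs = np.array(tr["x"])[sel]
            assert np.allclose(xs, want, atol=1e-9)

    def test_excess_intensity_equals_stored_contour(self):
        """Summation oracle on noiseless frames: excess area = c_o * L_k."""
        prof = TrueProfileSpec.compressed(C_b=8.0, R_c=0.2)
        knots = [KnotSpec(7.0, 1.2, 2.0, diffusivity=0.0)]
        spec = KymographSpec(profile=prof, knots=knots, seed=0,
                             noise_model=(0.0, 0.0))
        ky = gen_kymograph(spec)
        clean_spec = KymographSpec(profile=prof, knots=[], seed=0,
                                   noise_model=(0.0, 0.0))
        ky0 = gen_kymograph(clean_spec)
        hold = dict((n, b) for n, b in ky.truth["phases"])["hold"]
        fi = int(np.argmin(np.abs(ky.times - (hold[0] + 2.0))))
        px = ky.pixel_size
        excess = (ky.data[fi] - ky0.data[fi]).sum() * px
        assert excess == pytest.approx(2.0 * prof.c_o, rel=1e-3)

    def test_birth_time_outside_compression_rejected(self):
        prof = TrueProfileSpec.compressed(C_b=8.0, R_c=0.2)
        knots = [KnotSpec(0.5, 0.5, 1.0)]  # during equilibrium
        with pytest.raises(InvalidSpecError):
            gen_kymograph(KymographSpec(profile=prof, knots=knots, seed=0))

    def test_determinism_byte_identical(self):
        spec = sample_event_spec(2, seed=11)
        a = gen_kymograph(spec)
        b = gen_kymograph(sample_event_spec(2, seed=11))
        assert np.array_equal(a.data, b.data)

    def test_tiff_round_trip(self, tmp_path):
        ky = gen_kymograph(sample_event_spec(1, seed=5))
        path = tmp_path / "event.tiff"
        ky.to_tiff(path)
        back = ky.from_tiff(path)
        assert np.allclose(back.data, ky.data, atol=1e-6)
        assert back.truth["m_true"] == ky.truth["m_true"]


class TestKnotPositions:
    def test_single_knot_mean_matches_closed_form(self):
        lam = 0.25
        xs = gen_knot_positions(lam, m=1, n_events=10_000, seed=0)
        se = xs.std(ddof=1) / np.sqrt(xs.size)
        assert abs(xs.mean() - trunc_exp_mean(lam)) < 3 * se

    def test_flat_limit_is_uniform(self):
        from scipy.stats import kstest

        xs = gen_knot_positions(1e9, m=1, n_events=5000, seed=1)
        assert kstest(xs, "uniform").pvalue > 0.01

    def test_zero_gap_lower_knot_is_min_of_two(self):
        """Order-statistics oracle: with no gap the lower knot is the minimum
        of two iid truncated exponentials."""
        lam = 0.3
        pairs = gen_knot_positions(lam, gap=0.0, m=2, n_events=20_000, seed=2)
        rng = np.random.default_rng(3)
        u = rng.random((20_000, 2))
        z = 1.0 - np.exp(-1.0 / lam)
        iid = -lam * np.log1p(-u * z)
        oracle_lower = iid.min(axis=1)
        from scipy.stats import ks_2samp

        assert ks_2samp(pairs[:, 0], oracle_lower).pvalue > 0.01

    def test_gap_enforced(self):
        pairs = gen_knot_positions(0.3, gap=0.2, m=2, n_events=2000, seed=4)
        assert np.all(pairs[:, 1] - pairs[:, 0] > 0.2)

    def test_infeasible_gap_raises(self):
        with pytest.raises(InvalidSpecError):
            gen_knot_positions(0.3, gap=1.0, m=2, n_events=10, seed=0)


class TestSpecConfigRoundTrip:
    def test_profile_spec_json(self, tmp_path):
        from knotfactory.synthetic import spec_to_json, spec_from_json

        spec = TrueProfileSpec.compressed(C_b=8.0, R_c=0.2, t_w=12.0)
        path = tmp_path / "spec.json"
        spec_to_json(spec, path)
        back = spec_from_json(path)
        assert back == spec

    def test_kymograph_spec_json(self, tmp_path):
        from knotfactory.synthetic import spec_to_json, spec_from_json

        spec = sample_event_spec(2, seed=5)
        path = tmp_path / "kymo.json"
        spec_to_json(spec, path)
        back = spec_from_json(path)
        assert back.knots == spec.knots
        assert back.profile == spec.profile
        assert np.array_equal(gen_kymograph(back).data, gen_kymograph(spec).data)
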