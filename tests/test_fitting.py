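"""Lookahead-model fitting: window statistics, grid search, step detection."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atcmlab import (DEFAULT_WEIGHTS, THORAX_PLAIN, FitParams,
                     ModulationCurve, WEDProfile, ctdi_vs_wed, detect_steps,
                     eval_model, fit_model, simulate_modulation,
                     window_stats)
from atcmlab.atcm_sim import window_stat_matrix


def brute_window_stats(values):
    """Independent oracle: explicit sort + linear-interpolation quartiles."""
    v = sorted(values)
    n = len(v)

    def quantile(q):
        h = (n - 1) * q
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return v[-1], quantile(0.75), quantile(0.5), v[0]


class TestWindowStats:
    def test_identical_values_collapse(self):
        prof = WEDProfile(z=np.arange(10.0), wed=np.full(10, 7.5))
        assert window_stats(prof, 5.0, 4, "FH", 1.0) == (7.5, 7.5, 7.5, 7.5)

    def test_textbook_quartiles(self):
        prof = WEDProfile(z=np.arange(4.0), wed=[10.0, 20.0, 30.0, 40.0])
        stats = window_stats(prof, 0.0, 4, "FH", 1.0)
        assert stats == (40.0, 32.5, 25.0, 10.0)

    def test_directions_see_different_windows(self):
        z = np.arange(21.0)
        prof = WEDProfile(z=z, wed=z ** 2)
        hf = window_stats(prof, 10.0, 5, "HF", 1.0)
        fh = window_stats(prof, 10.0, 5, "FH", 1.0)
        assert hf != fh
        assert fh[0] > hf[0]  # FH looks toward larger values here

    def test_positions_beyond_profile_pad_with_air(self):
        prof = WEDProfile(z=np.arange(5.0), wed=np.full(5, 100.0))
        stats = window_stats(prof, 4.0, 10, "FH", 1.0)
        assert stats[3] == 0.0 and stats[0] == 100.0

    def test_empty_window_rejected(self):
        prof = WEDProfile(z=np.arange(5.0), wed=np.ones(5))
        with pytest.raises(ValueError):
            window_stats(prof, 2.0, 0, "HF", 1.0)

    def test_bruteforce_equivalence_on_random_profiles(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            d = int(rng.integers(1, n + 1))
            vals = rng.uniform(0, 400, n)
            i = int(rng.integers(0, n - d + 1))
            expected = brute_window_stats(vals[i:i + d])
            got = window_stat_matrix(vals, d)[i]
            np.testing.assert_allclose(got, expected, rtol=0, atol=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0, 500), min_size=1, max_size=30))
    def test_matrix_first_row_matches_oracle(self, values):
        d = len(values)
        got = window_stat_matrix(np.array(values), d)[0]
        np.testing.assert_allclose(got, brute_window_stats(values),
                                   rtol=0, atol=1e-9)


class TestEvalModel:
    def test_zero_slope_collapses_to_offset(self):
        assert eval_model((2.0, 0.0, 3.0), 123.4) == pytest.approx(5.0)

    def test_closed_form_value(self):
        assert eval_model((1.0, 0.01, 2.0), 100.0) == pytest.approx(
            math.e + 2.0, abs=1e-4)

    def test_strictly_increasing_for_positive_a_b(self):
        f = np.linspace(0, 400, 50)
        y = eval_model((0.5, 0.01, 1.0), f)
        assert np.all(np.diff(y) > 0)

    def test_overflow_guarded(self):
        assert np.isfinite(eval_model((1.0, 10.0, 0.0), 1e6))


class TestFitModel:
    def test_exact_recovery_on_noise_free_data(self, unclamped_fit,
                                               unclamped_protocol):
        curve, result = unclamped_fit
        p = unclamped_protocol
        assert result.params.d == 20
        true_a = p.k_dose * p.reference_mas * math.exp(
            -p.modulation_strength * p.beta * p.wed_ref)
        true_b = p.modulation_strength * p.beta
        assert result.params.a == pytest.approx(true_a, rel=0.01)
        assert result.params.b == pytest.approx(true_b, rel=0.01)
        assert abs(result.params.c) < 0.01 * true_a
        np.testing.assert_allclose(result.params.weights, DEFAULT_WEIGHTS,
                                   rtol=0.01)
        assert result.rmse < 1e-8
        assert result.r2 > 0.999999

    def test_reported_d_minimizes_grid(self, p08_fit):
        grid = p08_fit.d_grid_profile
        assert p08_fit.params.d == min(grid, key=grid.get)
        assert set(grid) == set(range(1, 41))

    def test_weight_simplex_constraints(self, p08_fit, unclamped_fit,
                                        pitch_sweep_fits):
        fits = [p08_fit, unclamped_fit[1], *pitch_sweep_fits.values()]
        for res in fits:
            w = np.asarray(res.params.weights)
            assert abs(w.sum() - 1.0) <= 1e-9
            assert np.all(w >= -1e-12)

    def test_shared_fit_of_mirror_curves(self):
        z = np.arange(-250.0, 250.1, 2.0)
        wed = 250.0 - np.abs(z) * 0.5  # symmetric tent profile
        prof = WEDProfile(z=z, wed=np.clip(wed, 0, None))
        proto = replace(THORAX_PLAIN, min_ma=0.0, max_ma=1e9)
        hf = simulate_modulation(prof, proto, "HF", 40.0)
        fh = simulate_modulation(prof, proto, "FH", 40.0)
        res = fit_model([(hf, prof), (fh, prof)],
                        d_candidates=range(10, 31))
        assert res.params.d == 20
        assert res.r2 > 0.99
        assert len(res.per_curve_residuals) == 2

    def test_unshared_returns_per_curve_fits(self, mercury_profile):
        hf = simulate_modulation(mercury_profile, THORAX_PLAIN, "HF", 40.0)
        fh = simulate_modulation(mercury_profile, THORAX_PLAIN, "FH", 40.0)
        results = fit_model([(hf, mercury_profile), (fh, mercury_profile)],
                            d_candidates=[18, 20, 22], shared=False)
        assert len(results) == 2
        assert all(r.params.d == 20 for r in results)

    def test_degenerate_flat_curve_flagged(self):
        prof = WEDProfile(z=np.arange(50.0) * 2, wed=np.full(50, 200.0))
        curve = ModulationCurve(
            z=np.arange(50.0) * 2, ctdi_vol=np.full(50, 3.0),
            ma=np.full(50, 100.0), direction="FH", protocol=THORAX_PLAIN)
        res = fit_model([(curve, prof)], d_candidates=[1, 2])
        assert res.degenerate
        assert res.params.b == 0.0
        assert res.params.c == pytest.approx(3.0)

    def test_noise_robust_depth_recovery(self, mercury_profile):
        # 5% multiplicative dose noise; depth must stay within one slice
        # of the generator's 20-slice window in at least 90% of replicates
        base = simulate_modulation(mercury_profile, THORAX_PLAIN, "HF",
                                   40.0)
        hits = 0
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            noisy = replace(base, ctdi_vol=base.ctdi_vol *
                            (1.0 + 0.05 * rng.standard_normal(len(base))))
            res = fit_model([(noisy, mercury_profile)],
                            d_candidates=range(1, 41))
            hits += abs(res.params.d - 20) <= 1
        assert hits >= 0.9 * reps


class TestDetectSteps:
    @staticmethod
    def staircase(widths, levels, dz=2.0, lead=30.0):
        edges_z = np.cumsum([lead] + list(widths))
        z = np.arange(0.0, edges_z[-1] + lead, dz)
        y = np.full(z.size, levels[0])
        for e, lv in zip(edges_z, levels[1:]):
            y[z >= e] = lv
        return ModulationCurve(z=z, ctdi_vol=y, ma=y * 10, direction="FH",
                               protocol=THORAX_PLAIN)

    def test_flat_curve_has_no_steps(self):
        curve = self.staircase([], [3.0])
        assert detect_steps(curve, min_step=0.5) == []

    def test_known_plateau_widths_recovered(self):
        widths = [14.0, 16.0, 20.0]
        # lead plateau, the three plateaus under test, and a tail plateau
        curve = self.staircase(widths, [2.0, 4.0, 6.5, 9.0, 11.5], dz=2.0)
        steps = detect_steps(curve, min_step=1.0)
        got = [w for _, w in steps[:-1]]
        np.testing.assert_allclose(got, widths, atol=2.0)

    def test_single_step_edge_position(self):
        curve = self.staircase([40.0], [2.0, 5.0], dz=2.0, lead=30.0)
        steps = detect_steps(curve, min_step=1.0)
        assert len(steps) == 1
        assert steps[0][0] == pytest.approx(30.0, abs=2.0)


class TestCtdiVsWed:
    def test_pairs_count_equals_slice_count(self, hf_curve,
                                            mercury_profile):
        df = ctdi_vs_wed(hf_curve, mercury_profile)
        assert len(df) == len(hf_curve)
        assert set(df["direction"]) == {"HF"}

    def test_unit_lookahead_scatter_lies_on_model(self):
        z = np.arange(0.0, 300.0, 2.0)
        prof = WEDProfile(z=z, wed=150.0 + z / 3.0)  # monotone profile
        proto = replace(THORAX_PLAIN, min_ma=0.0, max_ma=1e9)
        curve = simulate_modulation(prof, proto, "FH", proto.recon_thickness,
                                    table_positions=z)
        df = ctdi_vs_wed(curve, prof)
        a = proto.k_dose * proto.reference_mas * math.exp(
            -proto.modulation_strength * proto.beta * proto.wed_ref)
        b = proto.modulation_strength * proto.beta
        np.testing.assert_allclose(df["ctdi_vol_mGy"],
                                   eval_model((a, b, 0.0), df["wed_mm"]),
                                   rtol=1e-12)

    def test_directions_give_different_scatters(self, mercury_profile):
        hf = simulate_modulation(mercury_profile, THORAX_PLAIN, "HF", 40.0)
        fh = simulate_modulation(mercury_profile, THORAX_PLAIN, "FH", 40.0)
        a = ctdi_vs_wed(hf, mercury_profile).sort_values("table_position_mm")
        b = ctdi_vs_wed(fh, mercury_profile).sort_values("table_position_mm")
        assert not np.allclose(a["ctdi_vol_mGy"].to_numpy(),
                               b["ctdi_vol_mGy"].to_numpy())


def test_fit_params_validation():
    with pytest.raises(ValueError):
        FitParams(1.0, 0.01, 0.0, -1, (0.25, 0.25, 0.25, 0.25))
    with pytest.raises(ValueError):
        FitParams(1.0, 0.01, 0.0, 5, (0.5, 0.5, 0.5, 0.5))
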