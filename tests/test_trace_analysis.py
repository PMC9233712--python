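"""Trace/image quantification pipeline unit and oracle tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from epiextrude.trace_analysis import (
    AlignedEnsemble,
    EliminationCounts,
    TraceSeries,
    align_normalize,
    apicobasal_profile,
    compare_groups,
    contraction_rate,
    contraction_yield,
    detect_onset,
    detect_pulses,
    duration_histogram,
    elimination_stats,
    extrusion_duration,
    fisher_exact_two_sided,
    perimeter_fold_change,
    pulse_frequency,
    radial_kymograph,
    rate_of_change,
    region_intensities,
    smooth_trace,
    xcorr_normalized,
)


def tr(values, dt=1.0, **kw):
    values = np.asarray(values, float)
    return TraceSeries(np.arange(len(values)) * dt, values, **kw)


class TestTraceSeries:
    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError):
            TraceSeries(np.array([0.0, 1.0, 3.0]), np.zeros(3))

    def test_gap_interpolation(self):
        t = tr([1.0, np.nan, 3.0, 4.0])
        assert np.allclose(t.interpolate_gaps().values, [1, 2, 3, 4])

    def test_long_gap_rejected(self):
        t = tr([1.0, np.nan, np.nan, np.nan, 5.0])
        with pytest.raises(ValueError):
            t.interpolate_gaps(max_gap=2)


class TestSmoothTrace:
    def test_constant_trace_unchanged(self):
        t = tr(np.full(30, 7.0))
        for method, span in (("moving_average", 5), ("loess", 0.07)):
            assert np.allclose(smooth_trace(t, method, span).values, 7.0)

    def test_linear_ramp_fixed_point_of_moving_average(self):
        t = tr(3.0 * np.arange(40) + 1)
        sm = smooth_trace(t, "moving_average", 5)
        assert np.allclose(sm.values, t.values, atol=1e-12)

    def test_unit_impulse_spread(self):
        v = np.zeros(21)
        v[10] = 1.0
        sm = smooth_trace(tr(v), "moving_average", 5)
        assert np.allclose(sm.values[8:13], 0.2)
        assert sm.values[7] == 0 and sm.values[13] == 0

    def test_bad_parameters_rejected(self):
        t = tr(np.arange(10.0))
        with pytest.raises(ValueError):
            smooth_trace(t, "moving_average", 0)
        with pytest.raises(ValueError):
            smooth_trace(t, "loess", -0.1)


def onset_oracle(trace: TraceSeries, min_segment=5):
    """Independent exhaustive two-segment least-squares breakpoint: naive
    smoothing + np.polyfit per candidate."""
    n = len(trace)
    y = np.array(
        [
            trace.values[max(0, i - min(2, i, n - 1 - i)) : i + min(2, i, n - 1 - i) + 1].mean()
            for i in range(n)
        ]
    )
    x = trace.times
    best, best_sse = None, np.inf
    for b in range(min_segment, n - min_segment + 1):
        sse = 0.0
        for xx, yy in ((x[:b], y[:b]), (x[b:], y[b:])):
            coef = np.polyfit(xx, yy, 1)
            sse += float(np.sum((np.polyval(coef, xx) - yy) ** 2))
        if sse < best_sse:
            best, best_sse = b, sse
    return best


class TestDetectOnset:
    def test_plateau_then_decline(self):
        v = np.concatenate([np.full(100, 100.0), 100 - 2 * np.arange(1, 51)])
        r = detect_onset(tr(v))
        assert r.index is not None and abs(r.index - 100) <= 3

    def test_pure_linear_flagged(self):
        r = detect_onset(tr(100 - 2 * np.arange(60.0)))
        assert r.no_constriction and r.index is None

    def test_flat_trace_flagged(self):
        r = detect_onset(tr(np.full(40, 50.0)))
        assert r.no_constriction

    def test_matches_exhaustive_oracle(self):
        """Identical breakpoint to the independent oracle on noisy traces
        of length <= 60."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(20, 61))
            onset = int(rng.integers(6, n - 6))
            v = np.where(
                np.arange(n) < onset, 100.0, 100.0 - 2.0 * (np.arange(n) - onset)
            )
            v = v + rng.normal(0, 3, n)
            t = tr(v)
            r = detect_onset(t)
            assert r.candidates[int(np.argmin(r.error_curve))] == onset_oracle(t)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_onset(tr(np.arange(8.0)))


class TestAlignNormalize:
    def test_first5_normalisation(self):
        t = tr([10.0] * 5 + [20.0, 30.0])
        ens = align_normalize([t], mode="end")
        np.testing.assert_allclose(ens.matrix[0], [1, 1, 1, 1, 1, 2, 3])

    def test_end_alignment_of_offset_twins(self):
        a = TraceSeries(np.arange(10.0), np.arange(10.0))
        b = TraceSeries(np.arange(10.0) + 5.0, np.arange(10.0))
        ens = align_normalize([a, b], mode="end", norm="none")
        assert ens.rel_times[-1] == 0.0
        np.testing.assert_allclose(ens.matrix[0], ens.matrix[1])

    def test_onset_alignment(self):
        traces = [tr(np.r_[np.full(k, 10.0), 10 - np.arange(1, 8.0)]) for k in (5, 9)]
        ens = align_normalize(traces, mode="onset", norm="none", references=[5, 9])
        i0 = int(np.flatnonzero(ens.rel_times == 0.0)[0])
        # both traces show the same (first post-onset) value at rel time 0
        assert np.all(ens.matrix[:, i0] == 9.0)
        np.testing.assert_allclose(ens.matrix[0, i0 - 2 : i0 + 3],
                                   ens.matrix[1, i0 - 2 : i0 + 3])

    def test_zero_norm_excluded(self):
        good = tr([2.0] * 10)
        bad = tr([0.0] * 5 + [1.0] * 5)
        ens = align_normalize([good, bad], mode="end")
        assert ens.matrix.shape[0] == 1


class TestRateOfChange:
    def test_contraction_rate_sign(self):
        rate = contraction_rate(tr([10.0, 8.0, 6.0]))
        np.testing.assert_allclose(rate.values, [2.0, 2.0])
        np.testing.assert_allclose(rate.times, [0.5, 1.5])

    def test_constant_trace_zero(self):
        assert np.all(rate_of_change(tr(np.full(10, 3.0))).values == 0)

    def test_integral_reconstructs_total_change(self):
        rng = np.random.default_rng(4)
        v = rng.normal(50, 5, 80)
        t = tr(v, dt=5.0)
        rate = contraction_rate(t)
        assert -np.sum(rate.values) * 5.0 == pytest.approx(v[-1] - v[0], abs=1e-9)


class TestXcorr:
    def test_identity_peak_at_zero(self):
        a = tr(np.sin(np.arange(50) / 3.0))
        lags, coefs, best = xcorr_normalized(a, a)
        assert best == 0.0
        assert coefs[np.flatnonzero(lags == 0)[0]] == pytest.approx(1.0)

    def test_shift_recovered(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 200)
        a = tr(base)
        b = tr(np.roll(base, 3))  # b(t) = a(t-3)
        _, _, best = xcorr_normalized(a, b, max_lag=20)
        assert best == 3.0

    def test_null_simulation_bounded(self):
        """Independent white-noise pairs rarely exceed |coef| 0.2."""
        rng = np.random.default_rng(6)
        ok = 0
        for _ in range(40):
            a = tr(rng.normal(0, 1, 500))
            b = tr(rng.normal(0, 1, 500))
            _, coefs, _ = xcorr_normalized(a, b, max_lag=20)
            ok += np.max(np.abs(coefs)) < 0.2
        assert ok >= 38  # >= 95%

    def test_coefficients_bounded_and_antisymmetric(self):
        rng = np.random.default_rng(7)
        a = tr(rng.normal(0, 1, 60))
        b = tr(rng.normal(0, 1, 60))
        lags_ab, c_ab, _ = xcorr_normalized(a, b, max_lag=15)
        lags_ba, c_ba, _ = xcorr_normalized(b, a, max_lag=15)
        assert np.all(np.abs(c_ab) <= 1 + 1e-12)
        np.testing.assert_allclose(c_ab, c_ba[::-1], atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            xcorr_normalized(tr(np.ones(10)), tr(np.arange(10.0)))


class TestDetectPulses:
    @staticmethod
    def gaussian_bump(amp=10.0, sigma=2.0, n=61, centre=30):
        x = np.arange(n, dtype=float)
        return amp * np.exp(-0.5 * ((x - centre) / sigma) ** 2)

    def test_single_gaussian_metrics(self):
        pulses = detect_pulses(tr(self.gaussian_bump()), min_prominence=7)
        assert len(pulses) == 1
        p = pulses.pulses[0]
        assert p.t_peak == 30.0
        assert p.a_peak == pytest.approx(10.0, rel=1e-6)
        assert p.w_peak == pytest.approx(2.355 * 2.0, rel=0.02)

    def test_subthreshold_bump_ignored(self):
        pulses = detect_pulses(tr(self.gaussian_bump(amp=5.0)), min_prominence=7)
        assert len(pulses) == 0

    def test_two_bumps_ordered(self):
        v = self.gaussian_bump(n=121, centre=30) + self.gaussian_bump(n=121, centre=85)
        pulses = detect_pulses(tr(v), min_prominence=7)
        assert [p.t_peak for p in pulses] == [30.0, 85.0]

    @given(st.floats(min_value=-50, max_value=50))
    @settings(deadline=None, derandomize=True)
    def test_prominence_invariant_to_offset(self, offset):
        v = self.gaussian_bump() + offset
        pulses = detect_pulses(tr(v), min_prominence=7)
        assert len(pulses) == 1
        assert pulses.pulses[0].a_peak == pytest.approx(10.0, rel=1e-6)

    def test_metrics_invariant_to_time_translation(self):
        v = self.gaussian_bump()
        p1 = detect_pulses(tr(v), 7).pulses[0]
        shifted = TraceSeries(np.arange(61.0) + 40.0, v)
        p2 = detect_pulses(shifted, 7).pulses[0]
        assert p2.t_peak - p1.t_peak == 40.0
        assert p2.a_peak == p1.a_peak and p2.w_peak == p1.w_peak


class TestPulseFrequency:
    def test_counts_per_minute(self):
        pulses = detect_pulses(
            tr(
                sum(
                    TestDetectPulses.gaussian_bump(n=200, centre=c)
                    for c in (10, 30, 50, 70)
                )
            ),
            min_prominence=5,
        )
        before, after = pulse_frequency(pulses, onset_time=80.0, trace_span=(0.0, 199.0))
        assert before == pytest.approx(4 / 80)
        assert after == pytest.approx(0.0)

    def test_empty_pulses(self):
        from epiextrude.trace_analysis import PulseSet

        assert pulse_frequency(PulseSet([]), 10.0, (0.0, 20.0)) == (0.0, 0.0)

    def test_poisson_rate_recovered(self):
        """Mean recovered frequency within 15% of the generating rate."""
        from epiextrude.synthetic_data import SynthCohortSpec, gen_pulsatile_pair

        lam = 0.1
        freqs = []
        for i in range(100):
            spec = SynthCohortSpec(
                pulse_rate=lam, duration_min=200.0, noise_sd=0.5,
                pulse_sigma_min=1.0, pulse_min_gap_min=5.0,
                onset_min=100.0, seed=8,
            )
            m, _, truth = gen_pulsatile_pair(spec, stream=i)
            pulses = detect_pulses(m, min_prominence=3)
            f_b, f_a = pulse_frequency(pulses, 100.0, (m.times[0], m.times[-1]))
            freqs.append((f_b + f_a) / 2)
        assert np.mean(freqs) == pytest.approx(lam, rel=0.15)


class TestContractionYield:
    def test_bin_edges(self):
        assert math.floor(-7 / 5) * 5 == -10  # peak at -7 min -> bin [-10, -5)
        assert math.floor(2 / 5) * 5 == 0

    def test_simple_ratio(self):
        # one clean contraction bump: rate peak / myosin value there
        x = np.arange(0.0, 60.0)
        rate = 1.5 * np.exp(-0.5 * ((x - 30) / 3.0) ** 2)
        perimeter = 100 - np.concatenate([[0], np.cumsum(rate[:-1])])
        myosin = np.full_like(x, 3.0)
        y = contraction_yield(
            tr(perimeter), tr(myosin), onset_time=20.0, min_prominence=0.5, smooth_span=0.05
        )
        assert len(y) == 1
        assert y["yield"].iloc[0] == pytest.approx(0.5, rel=0.05)
        assert y["bin_left"].iloc[0] == 10.0  # peak ~30 min, onset 20 -> bin [10, 15)


class TestRadialKymograph:
    def test_ring_lands_in_its_bin(self):
        img = np.zeros((1, 40, 40))
        c = (40 - 1) / 2
        yy, xx = np.mgrid[0:40, 0:40]
        rr = np.hypot(yy - c, xx - c)
        img[0][(rr >= 10) & (rr < 13)] = 1.0
        k = radial_kymograph(img, np.array([c, c]), ring_width=3.0)
        bins = k.bin_centers
        hot = int(np.argmax(k.grid[0]))
        assert bins[hot] == pytest.approx(11.5343, abs=1.5 + 1e-9) or 10 <= bins[hot] <= 13
        cold = int(np.flatnonzero((bins >= 4) & (bins <= 7))[0])
        assert k.grid[0][cold] == 0.0

    def test_uniform_image(self):
        img = np.full((2, 32, 32), 4.2)
        k = radial_kymograph(img, np.array([15.5, 15.5]))
        inside = k.counts[0] > 0
        np.testing.assert_allclose(k.grid[0][inside], 4.2)

    def test_mass_conserved(self):
        """Count-weighted bin sums equal the pixel sum over the covered
        disk within 1%."""
        rng = np.random.default_rng(9)
        img = rng.random((1, 48, 48))
        k = radial_kymograph(img, np.array([23.5, 23.5]))
        covered = np.nansum(k.grid[0] * k.counts[0])
        assert covered == pytest.approx(img.sum(), rel=0.01)

    def test_centre_outside_skipped(self):
        img = np.ones((2, 16, 16))
        k = radial_kymograph(img, np.array([[8.0, 8.0], [99.0, 8.0]]))
        assert np.isfinite(k.contour_radius[0])
        assert np.isnan(k.contour_radius[1])


class TestRegionIntensities:
    @staticmethod
    def disk_mask(size=48, r=20):
        yy, xx = np.mgrid[0:size, 0:size]
        return np.hypot(yy - size / 2, xx - size / 2) <= r

    def test_uniform_disk(self):
        mask = self.disk_mask()
        img = np.where(mask, 5.0, 0.0)
        out = region_intensities(mask, img)
        assert out["medial"] == pytest.approx(5.0)
        assert 0 < out["junctional"] < 5.0

    def test_ring_only_signal(self):
        mask = self.disk_mask()
        band = mask & ~self.disk_mask(r=17)
        img = np.where(band, 10.0, 0.0)
        out = region_intensities(mask, img)
        # the 3-px erosion can graze the band's innermost pixels, so
        # "medial ~ 0" is relative to the ring intensity of 10
        assert out["medial"] < 0.5
        assert out["junctional"] > 2.0

    def test_background_subtraction(self):
        mask = self.disk_mask()
        img = np.where(mask, 10.0, 2.0) + 0.0
        bg = np.full((20, 20), 2.0)
        out = region_intensities(mask, img, background_roi=bg)
        assert out["medial"] == pytest.approx(8.0)

    def test_emptied_medial_flagged(self):
        mask = self.disk_mask(size=10, r=2)
        out = region_intensities(mask, np.ones((10, 10)))
        assert np.isnan(out["medial"])


class TestApicobasalProfile:
    def test_reference_max_maps_to_zero(self):
        ref = [np.array([0, 1, 2, 3, 9, 3, 2])]
        sig = [np.array([2.0, 6.0, 10.0, 4, 3, 2, 1])]
        df = apicobasal_profile(ref, sig)
        assert df.loc[df.rel_z == 0, "n"].iloc[0] == 1
        # plane 4 (ref max) sits at rel_z 0
        assert df.rel_z.min() == -4 and df.rel_z.max() == 2

    def test_min_max_normalisation(self):
        ref = [np.array([1.0, 5.0, 1.0])]
        sig = [np.array([2.0, 6.0, 10.0])]
        df = apicobasal_profile(ref, sig)
        np.testing.assert_allclose(df["mean"].to_numpy(), [0.0, 0.5, 1.0])

    def test_jittered_maxima_realign(self):
        rng = np.random.default_rng(10)
        refs, sigs = [], []
        for _ in range(12):
            shift = int(rng.integers(-2, 3))
            ref = np.zeros(11)
            ref[5 + shift] = 10.0
            refs.append(ref)
            sigs.append(np.roll(np.linspace(0, 1, 11), shift))
        df = apicobasal_profile(refs, sigs)
        assert int(df.loc[df.n == 12, "rel_z"].abs().min()) == 0


class TestFoldChangeAndDurations:
    def test_fold_change(self):
        assert perimeter_fold_change(10.0, 12.0) == pytest.approx(1.2)
        assert perimeter_fold_change(7.0, 7.0) == 1.0
        with pytest.raises(ValueError):
            perimeter_fold_change(0.0, 5.0)

    def test_duration(self):
        assert extrusion_duration(30.0, 60.0) == 30.0
        with pytest.raises(ValueError):
            extrusion_duration(60.0, 30.0)

    def test_histogram_fractions(self):
        h = duration_histogram([10.0, 20.0, 30.0], bin_width=10.0)
        np.testing.assert_allclose(h["fraction"], [1 / 3, 1 / 3, 1 / 3])
        assert h["fraction"].sum() == pytest.approx(1.0)


def fisher_brute_force(table):
    """Independent oracle: enumerate all same-margin tables, sum the
    probabilities of those no more probable than the observed."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    probs = []
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs.append((k, math.comb(r1, k) * math.comb(r2, c1 - k)))
    obs = dict(probs)[a]
    return sum(w for _, w in probs if w <= obs) / math.comb(n, c1)


class TestEliminationStats:
    def test_published_example_table(self):
        p = fisher_exact_two_sided([[9, 1], [1, 9]])
        assert p == 202 / 184756
        assert p == pytest.approx(1.09e-3, abs=5e-6)

    def test_identical_rows_p_one(self):
        assert fisher_exact_two_sided([[5, 5], [5, 5]]) == 1.0

    def test_matches_brute_force_and_scipy(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            n = int(rng.integers(4, 201))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n - a + 1))
            c = int(rng.integers(0, n - a - b + 1))
            d = n - a - b - c
            table = [[a, b], [c, d]]
            mine = fisher_exact_two_sided(table)
            assert mine == pytest.approx(fisher_brute_force(table), abs=1e-12)
            assert mine == pytest.approx(scipy_fisher(table)[1], abs=1e-9)

    def test_proportions_and_ci(self):
        counts = [
            EliminationCounts("clone", 5, 100),
            EliminationCounts("wt", 1, 100),
        ]
        df = elimination_stats(counts)
        assert df.loc[df.compartment == "clone", "proportion"].iloc[0] == 0.05
        row = df[df.compartment == "clone"].iloc[0]
        assert row.ci_low < 0.05 < row.ci_high
        p = df.attrs["fisher_p"][("clone", "wt")]
        assert p == pytest.approx(scipy_fisher([[5, 95], [1, 99]])[1], abs=1e-9)

    def test_zero_cells_flagged(self):
        df = elimination_stats([EliminationCounts("empty", 0, 0)])
        assert np.isnan(df["proportion"].iloc[0])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            EliminationCounts("x", 5, 3)


class TestCompareGroups:
    def test_identical_nonnormal_samples_rank_path(self):
        a = [1.0, 1.0, 2.0, 2.0, 3.0, 10.0, 30.0, 100.0, 300.0]
        out = compare_groups(a, list(a))
        assert out["test"] == "mann-whitney"
        assert out["p_value"] == pytest.approx(1.0, abs=0.05)

    def test_gaussian_shift_takes_t_path_with_power(self):
        """2-SD shift at n=30: t path fires and p < 0.01 in >= 95% of
        simulations."""
        rng = np.random.default_rng(13)
        t_path, significant = 0, 0
        for _ in range(60):
            a = rng.normal(0, 1, 30)
            b = rng.normal(2, 1, 30)
            out = compare_groups(a, b)
            t_path += out["test"] == "t"
            significant += out["p_value"] < 0.01
        assert t_path >= 54
        assert significant >= 57

    def test_heavy_tails_take_rank_path(self):
        rng = np.random.default_rng(14)
        hits = 0
        for _ in range(30):
            a = rng.standard_cauchy(40)
            b = rng.standard_cauchy(40)
            hits += compare_groups(a, b)["test"] == "mann-whitney"
        assert hits >= 27

    def test_paired_design(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 1, 20)
        out = compare_groups(a, a + rng.normal(0.1, 0.05, 20), design="paired")
        assert out["test"] in ("paired t", "wilcoxon signed-rank")

    def test_constant_sample_flagged(self):
        out = compare_groups([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert out["degenerate_variance"]

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])
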