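"""Unit tests for amperometry/microdialysis trace quantification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dopaquant.synth import TraceSpec, generate_trace
from dopaquant.synth.traces import transient_auc_analytic
from dopaquant.traces import (
    Calibration,
    StimulusTrain,
    Trace,
    area_under_curve,
    average_sweeps,
    current_to_concentration,
    concentration_to_current,
    dat_block_comparison,
    fit_calibration,
    kcl_response,
    normalize_microdialysis,
    peak_amplitude,
    remove_stimulus_artefacts,
    rise_time_20_80,
    train_amplitudes,
)

RATE = 10_000.0


def make_trace(values, rate=RATE, start=0.0, units="uM"):
    return Trace(np.asarray(values, dtype=float), rate, start, units)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


class TestCalibration:
    def test_exact_linear_ladder(self):
        cal = fit_calibration([(0, 0), (1, 2), (5, 10), (10, 20), (20, 40)])
        assert cal.slope_na_per_um == pytest.approx(2.0)
        assert cal.intercept_na == pytest.approx(0.0)
        assert cal.r_squared == pytest.approx(1.0)
        assert cal.usable

    def test_matches_closed_form_normal_equations(self):
        # the standard 0/1/5/10/20 µM ladder with noisy currents
        conc = np.array([0.0, 1.0, 5.0, 10.0, 20.0])
        rng = np.random.default_rng(42)
        curr = 0.1 + 1.9 * conc + rng.normal(0, 0.2, conc.size)
        cal = fit_calibration(list(zip(conc, curr)))
        # closed-form least squares oracle
        n = conc.size
        sx, sy = conc.sum(), curr.sum()
        sxx, sxy = (conc**2).sum(), (conc * curr).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
        intercept = (sy - slope * sx) / n
        assert cal.slope_na_per_um == pytest.approx(slope, rel=1e-12)
        assert cal.intercept_na == pytest.approx(intercept, rel=1e-12)

    def test_dead_electrode_flagged_unusable(self):
        cal = fit_calibration([(0, 0), (1, 0), (5, 0)])
        assert cal.slope_na_per_um == pytest.approx(0.0)
        assert not cal.usable

    def test_too_few_distinct_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(5.0, 1.0), (5.0, 2.0)])

    def test_conversion_constant_trace(self):
        cal = Calibration(((0, 0), (1, 2)), 2.0, 0.0, 1.0, True)
        out = current_to_concentration(make_trace([4.0, 4.0, 4.0], units="nA"), cal)
        assert np.allclose(out.values, 2.0)
        assert out.units == "uM"
        assert out.meta["calibration"]["slope_na_per_um"] == 2.0

    def test_conversion_with_intercept(self):
        cal = Calibration(((0, 1), (1, 3)), 2.0, 1.0, 1.0, True)
        out = current_to_concentration(make_trace([1.0, 1.0], units="nA"), cal)
        assert np.allclose(out.values, 0.0)

    def test_conversion_round_trip_identity(self):
        cal = Calibration(((0, 0.3), (1, 2.3)), 2.0, 0.3, 1.0, True)
        trace = make_trace(np.sin(np.linspace(0, 5, 100)) + 1.5)
        back = current_to_concentration(concentration_to_current(trace, cal), cal)
        assert np.allclose(back.values, trace.values, atol=1e-12)

    def test_generated_current_recovers_noiseless_concentration(self):
        spec = TraceSpec(duration_s=1.0, stimulus_times_s=(0.2,), amplitude_um=(2.0,),
                         noise_sd_um=0.02, calibration_slope_na_per_um=1.9,
                         calibration_intercept_na=0.1, seed=7)
        current, conc, _ = generate_trace(spec)
        cal = Calibration(((0, 0.1), (1, 2.0)), 1.9, 0.1, 1.0, True)
        recovered = current_to_concentration(current, cal)
        resid = recovered.values - conc.values
        assert abs(np.mean(resid)) < 3 * 0.02 / math.sqrt(conc.n)
        assert np.std(resid) == pytest.approx(0.02, rel=0.1)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


class TestPreprocessing:
    def test_average_identical_sweeps_is_identity(self, flat_trace):
        out = average_sweeps([flat_trace] * 4)
        assert np.array_equal(out.values, flat_trace.values)

    def test_average_of_opposite_traces_is_zero(self):
        v = np.sin(np.linspace(0, 3, 50))
        out = average_sweeps([make_trace(v), make_trace(-v)])
        assert np.allclose(out.values, 0.0)

    def test_averaging_shrinks_noise_by_sqrt_n(self):
        rng = np.random.default_rng(0)
        clean = np.zeros(5000)
        noisy = [make_trace(clean + rng.normal(0, 1, 5000)) for _ in range(100)]
        sd_one = np.std(noisy[0].values)
        sd_avg = np.std(average_sweeps(noisy).values)
        assert sd_one / sd_avg == pytest.approx(10.0, rel=0.15)

    def test_average_rejects_mismatched_lengths(self, flat_trace):
        with pytest.raises(ValueError):
            average_sweeps([flat_trace, make_trace(np.ones(10))])

    def test_artefact_blanking_restores_flat_trace(self, flat_trace):
        spiked = make_trace(flat_trace.values.copy())
        spiked.values[5000] += 50.0
        stims = StimulusTrain((0.5,))
        out = remove_stimulus_artefacts(spiked, stims, blank_window_ms=1.0)
        assert np.allclose(out.values, 1.0)

    def test_no_stimuli_outside_trace_rejected(self, flat_trace):
        stims = StimulusTrain((flat_trace.end_time_s - 1e-5,))
        with pytest.raises(ValueError):
            remove_stimulus_artefacts(flat_trace, stims, blank_window_ms=1.0)

    def test_blanked_artefact_auc_matches_clean_generation(self):
        kw = dict(duration_s=1.0, stimulus_times_s=(0.2,), amplitude_um=(2.0,), seed=5)
        with_art, _, _ = generate_trace(TraceSpec(artefact_amplitude=100.0, **kw))
        without, _, _ = generate_trace(TraceSpec(artefact_amplitude=0.0, **kw))
        cleaned = remove_stimulus_artefacts(with_art, StimulusTrain((0.2,)), 1.0)
        auc_c = area_under_curve(cleaned, 0.2, 0.5)
        auc_0 = area_under_curve(without, 0.2, 0.5)
        assert auc_c == pytest.approx(auc_0, abs=5e-3 * abs(auc_0) + 1e-4)


# ---------------------------------------------------------------------------
# peak / rise / AUC
# ---------------------------------------------------------------------------


class TestPeakAndRise:
    def test_peak_of_single_transient(self, single_transient):
        _, _, conc, truth = single_transient
        peak = peak_amplitude(conc, (0.5, 1.0), baseline_window=(0.3, 0.45))
        assert peak == pytest.approx(truth.true_peak_um[0], abs=1e-3)

    def test_constant_trace_peak_zero(self, flat_trace):
        assert peak_amplitude(flat_trace, (1.0, 1.5), (0.1, 0.5)) == pytest.approx(0.0)

    @pytest.mark.parametrize("ramp_ms, expected_ms", [(1.0, 0.6), (2.0, 1.2)])
    def test_linear_ramp_rise_time(self, ramp_ms, expected_ms):
        # ramp 0 -> 1 µM over ramp_ms starting at 10 ms, then held
        rate = 100_000.0  # dense sampling so the ramp is exactly linear
        t = np.arange(int(0.05 * rate)) / rate
        v = np.clip((t - 0.01) / (ramp_ms / 1e3), 0, 1)
        tr = make_trace(v, rate=rate)
        rt = rise_time_20_80(tr, onset_s=0.01)
        assert rt == pytest.approx(expected_ms, abs=2e3 / rate)

    def test_rise_time_matches_root_finding_oracle(self):
        from scipy.optimize import brentq

        tau_r, tau_d = 0.5e-3, 50e-3
        spec = TraceSpec(duration_s=1.0, stimulus_times_s=(0.1,), amplitude_um=(1.0,),
                         tau_rise_ms=0.5, tau_decay_ms=50.0, seed=0)
        _, conc, _ = generate_trace(spec)
        measured = rise_time_20_80(conc, 0.1)
        # independent oracle: root-find the closed-form crossings
        t_peak = (tau_r * tau_d / (tau_d - tau_r)) * math.log(tau_d / tau_r)
        k = 1.0 / (math.exp(-t_peak / tau_d) - math.exp(-t_peak / tau_r))
        f = lambda t: k * (math.exp(-t / tau_d) - math.exp(-t / tau_r))  # noqa: E731
        t20 = brentq(lambda t: f(t) - 0.2, 1e-9, t_peak)
        t80 = brentq(lambda t: f(t) - 0.8, 1e-9, t_peak)
        assert measured == pytest.approx((t80 - t20) * 1e3, abs=1e3 / RATE)

    def test_rise_time_requires_positive_peak(self, flat_trace):
        with pytest.raises(ValueError):
            rise_time_20_80(flat_trace, 0.5, baseline_window=(0.1, 0.4))

    @given(scale=st.floats(0.1, 100), offset=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_rise_time_invariant_to_scale_and_offset(self, scale, offset):
        t = np.arange(2000) / RATE
        v = np.clip((t - 0.05) / 0.002, 0, 1) * np.exp(-np.clip(t - 0.052, 0, None) / 0.05)
        base = rise_time_20_80(make_trace(v), 0.05)
        transformed = rise_time_20_80(
            make_trace(scale * v + offset), 0.05, baseline_window=(0.0, 0.04)
        )
        assert transformed == pytest.approx(base, rel=1e-9)


class TestAuc:
    def test_rectangle(self):
        v = np.zeros(30_001)
        v[10_000:20_001] = 2.0
        auc = area_under_curve(make_trace(v), 1.0, 1.0)
        assert auc == pytest.approx(2.0, abs=1e-3)

    def test_zero_trace(self):
        assert area_under_curve(make_trace(np.zeros(100)), 0.0, 0.005) == 0.0

    def test_triangle(self):
        t = np.arange(30_001) / RATE
        v = np.interp(t, [0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert area_under_curve(make_trace(v), 0.0, 2.0) == pytest.approx(1.0, abs=1e-6)

    def test_additive_over_adjacent_windows(self, single_transient):
        _, _, conc, _ = single_transient
        whole = area_under_curve(conc, 0.4, 1.2)
        parts = area_under_curve(conc, 0.4, 0.37731) + area_under_curve(
            conc, 0.77731, 1.2 - 0.37731
        )
        assert whole == pytest.approx(parts, rel=1e-9)

    @given(scale=st.floats(0.01, 50))
    @settings(max_examples=25, deadline=None)
    def test_linear_in_amplitude(self, scale):
        rng = np.random.default_rng(1)
        v = rng.random(5000)
        base = area_under_curve(make_trace(v), 0.01, 0.4)
        assert area_under_curve(make_trace(scale * v), 0.01, 0.4) == pytest.approx(
            scale * base, rel=1e-9
        )

    def test_window_exceeding_trace_rejected(self, flat_trace):
        with pytest.raises(ValueError):
            area_under_curve(flat_trace, 1.0, 10.0)


# ---------------------------------------------------------------------------
# trains, DAT block, KCl, microdialysis
# ---------------------------------------------------------------------------


class TestTrain:
    def test_identical_transients_normalize_to_one(self):
        spec = TraceSpec(duration_s=1.5, stimulus_times_s=tuple(0.2 + i / 10 for i in range(10)),
                         amplitude_um=(1.0,) * 10, tau_rise_ms=0.5, tau_decay_ms=8.0, seed=0)
        _, conc, _ = generate_trace(spec)
        resp = train_amplitudes(conc, StimulusTrain.regular(10, 10.0, 0.2), 1.0)
        assert np.allclose(resp.normalized, 1.0, atol=0.02)

    def test_halving_amplitudes(self):
        amps = tuple(1.0 * 0.5**i for i in range(5))
        spec = TraceSpec(duration_s=1.2, stimulus_times_s=tuple(0.2 + i / 10 for i in range(5)),
                         amplitude_um=amps, tau_rise_ms=0.5, tau_decay_ms=8.0, seed=0)
        _, conc, _ = generate_trace(spec)
        resp = train_amplitudes(conc, StimulusTrain.regular(5, 10.0, 0.2), resp_ref := 1.0)
        assert np.allclose(resp.normalized, amps, atol=0.02)

    def test_summation_recovered_with_local_baseline(self):
        # slow decay -> strong summation; local baseline prevents double counting
        spec = TraceSpec(duration_s=3.0, stimulus_times_s=tuple(0.2 + i / 10 for i in range(10)),
                         amplitude_um=(1.0,) * 10, tau_rise_ms=1.0, tau_decay_ms=60.0, seed=0)
        _, conc, truth = generate_trace(spec)
        resp = train_amplitudes(conc, StimulusTrain.regular(10, 10.0, 0.2), 1.0)
        assert np.allclose(resp.amplitudes_um, truth.true_peak_um, atol=0.03)

    def test_reference_must_be_positive(self, flat_trace):
        with pytest.raises(ValueError):
            train_amplitudes(flat_trace, StimulusTrain((0.5,)), 0.0)


class TestDatBlock:
    def test_identical_traces(self, single_transient):
        _, _, conc, _ = single_transient
        res = dat_block_comparison(conc, conc, (0.5, 1.5))
        assert res.subtracted_area_um_s == pytest.approx(0.0, abs=1e-12)
        assert res.fold_increase == pytest.approx(1.0)

    def test_known_areas(self):
        v1 = np.zeros(30_001); v1[:10_001] = 2.0
        v2 = np.zeros(30_001); v2[:10_001] = 5.0
        res = dat_block_comparison(make_trace(v1), make_trace(v2), (0.0, 1.0))
        assert res.area_baseline_um_s == pytest.approx(2.0, abs=1e-3)
        assert res.subtracted_area_um_s == pytest.approx(3.0, abs=2e-3)
        assert res.fold_increase == pytest.approx(2.5, rel=1e-3)

    def test_zero_baseline_area_fold_undefined(self):
        zeros = make_trace(np.zeros(100))
        ones = make_trace(np.ones(100))
        res = dat_block_comparison(zeros, ones, (0.0, 0.005))
        assert res.fold_increase is None
        assert res.subtracted_area_um_s > 0

    @pytest.mark.parametrize("scale", [2.0, 5.0, 10.0])
    def test_fold_matches_analytic_integral_ratio(self, scale):
        kw = dict(duration_s=4.0, stimulus_times_s=(0.1,), amplitude_um=(1.0,),
                  tau_rise_ms=1.0, tau_decay_ms=40.0, seed=0)
        _, base, _ = generate_trace(TraceSpec(**kw))
        _, drug, _ = generate_trace(TraceSpec(clearance_scale=scale, **kw))
        res = dat_block_comparison(base, drug, (0.1, 0.1 + 2.935))
        expect = transient_auc_analytic(1.0, 1e-3, scale * 40e-3, 2.935) / \
            transient_auc_analytic(1.0, 1e-3, 40e-3, 2.935)
        assert res.fold_increase == pytest.approx(expect, rel=5e-3)


class TestKclAndMicrodialysis:
    def test_rectangular_kcl_response(self):
        rate = 100.0
        n = int(230 * rate)
        v = np.zeros(n)
        v[int(10 * rate): int(20 * rate)] = 1.0
        tr = make_trace(v, rate=rate)
        peak, auc = kcl_response(tr, puff_start_s=10.0, puff_duration_s=10.0)
        assert peak == pytest.approx(1.0)
        assert auc == pytest.approx(10.0, rel=1e-2)

    def test_flat_trace_kcl(self):
        tr = make_trace(np.zeros(30_000), rate=100.0)
        peak, auc = kcl_response(tr, 10.0)
        assert peak == 0.0 and auc == 0.0

    def test_kcl_requires_coverage(self):
        tr = make_trace(np.zeros(100), rate=100.0)
        with pytest.raises(ValueError):
            kcl_response(tr, 0.0)

    def test_slow_transient_auc_matches_analytic(self):
        rate = 100.0
        t = np.arange(int(240 * rate)) / rate
        tau = 30.0
        v = np.where(t >= 10.0, np.exp(-(t - 10.0) / tau), 0.0)
        _, auc = kcl_response(make_trace(v, rate=rate), 10.0, puff_duration_s=10.0)
        expect = tau * (1 - math.exp(-210.0 / tau))
        assert auc == pytest.approx(expect, rel=5e-3)

    def test_microdialysis_simple_normalization(self):
        series = [(80.0, 2.0), (100.0, 2.0), (130.0, 4.0)]
        norm, logc = normalize_microdialysis(series)
        assert norm[-1][1] == pytest.approx(2.0)
        assert logc[0][1] == pytest.approx(0.0)

    def test_microdialysis_constant_series(self):
        series = [(t, 3.0) for t in range(60, 180, 15)]
        norm, logc = normalize_microdialysis(series)
        assert all(v == pytest.approx(1.0) for _, v in norm)
        assert all(v == pytest.approx(0.0) for _, v in logc)

    def test_microdialysis_reference_group(self):
        control = [(90.0, 2.0), (110.0, 2.0)]
        mutant = [(90.0, 1.0), (130.0, 0.5)]
        norm, _ = normalize_microdialysis(mutant, reference_series=control)
        assert norm[0][1] == pytest.approx(0.5)

    def test_microdialysis_lognormal_recovery(self):
        mu, sigma = 0.5, 0.3
        rng = np.random.default_rng(11)
        means = []
        for _ in range(20):
            times = np.arange(0, 180, 15.0)
            series = list(zip(times, np.exp(rng.normal(mu, sigma, times.size))))
            _, logc = normalize_microdialysis(series)
            ref_mean = np.mean([c for t, c in series if 76 <= t <= 120])
            means.append(np.mean([v for _, v in logc]) - (mu - math.log(ref_mean)))
        assert abs(np.mean(means)) < 3 * sigma / math.sqrt(12 * 20)

    def test_microdialysis_empty_reference_window_rejected(self):
        with pytest.raises(ValueError):
            normalize_microdialysis([(10.0, 1.0)], reference_window_min=(76, 120))

    def test_log_copy_refused_for_nonpositive(self):
        with pytest.raises(ValueError):
            normalize_microdialysis([(80.0, 1.0), (100.0, -0.5)])
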