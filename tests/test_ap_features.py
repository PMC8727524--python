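"""AP detection and excitability measures, against constructed geometries
and brute-force oracles."""

import math

import numpy as np
import pytest

from drgsim import ap_features as ap
from drgsim.ap_features import (
    ThresholdNotFound,
    ap_threshold,
    ap_waveform_measures,
    charge_transfer,
    count_aps,
    detect_aps,
    first_isi,
    latency,
    phase_plot,
    rheobase_ramp,
    sweep_features,
)

from conftest import make_sweep

DT = 0.025


def piecewise_v(t, nodes):
    """Voltage interpolated through (time, voltage) nodes."""
    tt = [n[0] for n in nodes]
    vv = [n[1] for n in nodes]
    return np.interp(t, tt, vv)


def two_slope_spike(slope1=1.0, slope2=10.0, v_knee=-40.0, t_knee=20.0, peak=40.0):
    """Linear rise at slope1 to (t_knee, v_knee), then slope2 up to a peak
    and symmetric descent back to rest."""
    v0 = v_knee - slope1 * t_knee
    t_peak = t_knee + (peak - v_knee) / slope2
    t_end = t_peak + (peak - v0) / slope2
    t = np.arange(0.0, t_end + 5.0, DT)
    v = piecewise_v(t, [(0, v0), (t_knee, v_knee), (t_peak, peak),
                        (t_end, v0), (t_end + 5.0, v0)])
    return make_sweep(t, v, protocol="step_family", onset_ms=0.0,
                      stim_end_ms=t[-1], amplitude_pA=50.0)


class TestDetection:
    def test_flat_trace_has_no_aps(self):
        t = np.arange(0.0, 100.0, DT)
        sw = make_sweep(t, np.full_like(t, -60.0), protocol="step_family",
                        onset_ms=10.0, stim_end_ms=90.0)
        assert detect_aps(sw).size == 0

    def test_counts_match_crossing_oracle_on_simulated_sweep(self, wt_step_sweeps):
        """Peak detection equals a -10 mV upward-crossing count (1 ms debounce)."""
        sw = wt_step_sweeps[3]  # 100 pA
        v = sw.v
        ups = np.flatnonzero((v[:-1] <= -10.0) & (v[1:] > -10.0))
        # debounce: merge crossings closer than 1 ms
        keep = [ups[0]]
        for u in ups[1:]:
            if (u - keep[-1]) * sw.dt >= 1.0:
                keep.append(u)
        assert detect_aps(sw).size == len(keep)

    def test_two_close_aps_detected_in_order(self):
        t = np.arange(0.0, 40.0, DT)
        v = np.full_like(t, -60.0)
        for t0 in (20.0, 25.0):
            v += 100.0 * np.exp(-((t - t0) / 0.5) ** 2)
        sw = make_sweep(t, v, protocol="step_family", onset_ms=0.0, stim_end_ms=40.0)
        peaks = detect_aps(sw)
        assert peaks.size == 2
        assert peaks[0] < peaks[1]


class TestThreshold:
    def test_constructed_crossing_at_knee(self):
        sw = two_slope_spike(slope1=1.0, slope2=10.0)
        peaks = detect_aps(sw)
        thr, thr_t = ap_threshold(sw, int(peaks[0]))
        assert thr == pytest.approx(-40.0, abs=0.3)
        assert thr_t == pytest.approx(20.0, abs=0.3)

    def test_no_crossing_raises(self):
        sw = two_slope_spike(slope1=2.0, slope2=4.0, peak=0.0)
        # force a detectable peak: raise the apex above -10 mV with slope 4
        peaks = detect_aps(sw)
        if peaks.size == 0:
            pytest.skip("construction yielded no detectable peak")
        with pytest.raises(ThresholdNotFound):
            ap_threshold(sw, int(peaks[0]))

    def test_matches_exhaustive_scan_on_simulated_ap(self, wt_step_sweeps):
        """Interpolated threshold within one sample of a brute-force scan of
        the sampled dV/dt series."""
        sw = wt_step_sweeps[3]
        peaks = detect_aps(sw)
        p = int(peaks[0])
        thr, thr_t = ap_threshold(sw, p)
        dv = np.gradient(sw.v, sw.t)
        j = p
        while j > 0 and sw.v[j - 1] <= sw.v[j]:
            j -= 1
        hits = [k for k in range(j, p) if dv[k] < 5.0 <= dv[k + 1]]
        k = hits[-1]
        assert sw.t[k] <= thr_t <= sw.t[k + 1]
        assert min(sw.v[k], sw.v[k + 1]) <= thr <= max(sw.v[k], sw.v[k + 1])


class TestWaveformGeometry:
    def test_triangular_ap_measures(self):
        """Symmetric triangle: threshold -40, peak +40, slopes ±20 mV/ms."""
        t_knee, peak = 10.0, 40.0
        sw = two_slope_spike(slope1=1.0, slope2=20.0, v_knee=-40.0,
                             t_knee=t_knee, peak=peak)
        p = int(detect_aps(sw)[0])
        f = ap_waveform_measures(sw, p)
        assert f.threshold == pytest.approx(-40.0, abs=0.5)
        assert f.amplitude == pytest.approx(80.0, abs=0.5)
        # 10-90% span: -32 -> +32 mV at 20 mV/ms = 3.2 ms each flank
        assert f.rise_time_10_90 == pytest.approx(3.2, abs=0.05)
        assert f.fall_time_90_10 == pytest.approx(3.2, abs=0.05)
        assert f.rising_speed == pytest.approx(20.0, rel=0.05)
        # +15 mV crossings: 2*(40-15)/20 = 2.5 ms
        assert f.duration_at_plus15 == pytest.approx(2.5, abs=0.05)

    def test_low_peak_has_undefined_duration(self):
        sw = two_slope_spike(slope1=1.0, slope2=20.0, peak=10.0)
        p = int(detect_aps(sw)[0])
        f = ap_waveform_measures(sw, p)
        assert math.isnan(f.duration_at_plus15)

    def test_features_are_pure(self, wt_step_sweeps):
        a = sweep_features(wt_step_sweeps[2])
        b = sweep_features(wt_step_sweeps[2])
        assert a == b


class TestSweepMeasures:
    def test_latency_is_threshold_time_minus_onset(self):
        sw = two_slope_spike(t_knee=30.0)
        sw.meta["onset_ms"] = 10.0
        assert latency(sw) == pytest.approx(20.0, abs=0.3)

    def test_latency_undefined_without_aps(self):
        t = np.arange(0.0, 100.0, DT)
        sw = make_sweep(t, np.full_like(t, -60.0), protocol="step_family",
                        onset_ms=10.0, stim_end_ms=90.0)
        assert math.isnan(latency(sw))

    def test_first_isi_between_first_two_peaks(self):
        t = np.arange(0.0, 400.0, DT)
        v = np.full_like(t, -60.0)
        for t0 in (250.0, 280.0, 330.0):
            v += 100.0 * np.exp(-((t - t0) / 0.5) ** 2)
        sw = make_sweep(t, v, protocol="step_family", onset_ms=200.0,
                        stim_end_ms=400.0)
        assert first_isi(sw) == pytest.approx(30.0, abs=0.1)

    def test_first_isi_undefined_for_single_ap(self):
        sw = two_slope_spike()
        assert math.isnan(first_isi(sw))

    def test_ramp_count_window_edge(self):
        """Only APs within 2 s of the ramp start count."""
        t = np.arange(0.0, 3500.0, 0.1)
        v = np.full_like(t, -60.0)
        ramp_start = 700.0
        for dt_ap in (1800.0, 1950.0, 2100.0):
            v += 100.0 * np.exp(-((t - (ramp_start + dt_ap)) / 0.5) ** 2)
        sw = make_sweep(t, v, protocol="ramp", onset_ms=200.0,
                        stim_end_ms=3400.0, ramp_start_ms=ramp_start,
                        ramp_slope_pA_per_ms=0.1, baseline_cross_ms=1200.0)
        assert count_aps(sw) == 2

    def test_step_counts_all_aps_in_step(self, wt_step_sweeps):
        sw = wt_step_sweeps[0]  # 25 pA: silent
        assert count_aps(sw) == 0

    def test_first_ap_only_policy(self, wt_step_sweeps):
        """Threshold/latency derive from AP #1 even with many APs."""
        sw = wt_step_sweeps[3]
        peaks = detect_aps(sw)
        assert peaks.size > 2
        f = sweep_features(sw)
        thr1, thr_t1 = ap_threshold(sw, int(peaks[0]))
        assert f.threshold == thr1
        assert f.latency == pytest.approx(thr_t1 - sw.meta["onset_ms"])
        assert len(f.per_ap) == 1

    def test_no_ap_sweep_flags_fields(self, wt_step_sweeps):
        f = sweep_features(wt_step_sweeps[0])
        assert f.n_aps == 0
        for val in (f.latency, f.first_isi, f.threshold, f.charge_transfer):
            assert math.isnan(val)


class TestChargeAndRheobase:
    def test_step_charge_is_rectangle_area(self):
        """50 pA step, threshold 100 ms after onset -> 5 pC."""
        t = np.arange(0.0, 400.0, DT)
        v = piecewise_v(t, [(0, -60), (200, -60), (300, -40), (301.5, 40),
                            (303, -60), (400, -60)])
        i = np.where((t >= 200) & (t < 340), 50.0, 0.0)
        sw = make_sweep(t, v, i, protocol="step_family", onset_ms=200.0,
                        stim_end_ms=340.0, amplitude_pA=50.0)
        q = charge_transfer(sw)
        assert q == pytest.approx(5.0, rel=1e-3)

    def test_ramp_charge_is_triangle_area(self):
        """0.1 pA/ms ramp, threshold 400 ms past the 0 pA crossing -> 8 pC."""
        t = np.arange(0.0, 2000.0, DT)
        cross = 700.0
        i = np.where(t >= 200.0, (t - cross) * 0.1, 0.0)
        v = piecewise_v(t, [(0, -60), (1100, -40), (1101.5, 40), (1103, -60),
                            (2000, -60)])
        sw = make_sweep(t, v, i, protocol="ramp", onset_ms=200.0,
                        stim_end_ms=2000.0, ramp_start_ms=200.0,
                        ramp_slope_pA_per_ms=0.1, baseline_cross_ms=cross)
        # threshold lands at t=1100 (dV/dt jumps from 0.02 to 53 mV/ms)
        assert charge_transfer(sw) == pytest.approx(0.5 * 40.0 * 400.0 / 1000.0,
                                                    rel=2e-3)
        assert rheobase_ramp(sw) == pytest.approx(40.0, rel=2e-3)

    def test_rheobase_norm_divides_by_capacitance(self, wt_ramp_sweep):
        f = sweep_features(wt_ramp_sweep)
        assert f.rheobase_norm == pytest.approx(
            f.rheobase / wt_ramp_sweep.meta["cm_pF"]
        )

    def test_step_charge_equals_amplitude_times_latency(self, wt_step_sweeps):
        """Cross-check of two independently computed features (0.1%)."""
        sw = wt_step_sweeps[2]  # 75 pA
        f = sweep_features(sw)
        expected = 75.0 * f.latency / 1000.0
        assert f.charge_transfer == pytest.approx(expected, rel=1e-3)


class TestPhasePlot:
    def test_crossing_matches_threshold(self, wt_step_sweeps):
        sw = wt_step_sweeps[2]
        p = int(detect_aps(sw)[0])
        thr, thr_t = ap_threshold(sw, p)
        v, dv = phase_plot(sw, window=(thr_t - 10.0, sw.t[p]))
        ups = np.flatnonzero((dv[:-1] < 5.0) & (dv[1:] >= 5.0))
        k = ups[-1]
        frac = (5.0 - dv[k]) / (dv[k + 1] - dv[k])
        v_cross = v[k] + frac * (v[k + 1] - v[k])
        assert v_cross == pytest.approx(thr, abs=0.1)

    def test_trajectory_closes_near_rest(self, wt_step_sweeps):
        sw = wt_step_sweeps[2]
        p = int(detect_aps(sw)[0])
        t_peak = sw.t[p]
        v, dv = phase_plot(sw, window=(t_peak - 8.0, t_peak + 15.0))
        assert abs(dv[0]) < 5.0
        assert abs(dv[-1]) < 5.0


class TestInvariances:
    def test_time_shift_invariance(self):
        sw = two_slope_spike()
        f0 = ap_waveform_measures(sw, int(detect_aps(sw)[0]))
        shifted = make_sweep(sw.t + 123.0, sw.v, sw.i, **sw.meta)
        f1 = ap_waveform_measures(shifted, int(detect_aps(shifted)[0]))
        assert f1.threshold == pytest.approx(f0.threshold, abs=1e-9)
        assert f1.rise_time_10_90 == pytest.approx(f0.rise_time_10_90, abs=1e-9)
        assert f1.duration_at_plus15 == pytest.approx(f0.duration_at_plus15, abs=1e-9)

    def test_double_rate_resampling_invariance(self, wt_params):
        """Features stable under 2x finer recorded sampling (0.1 mV / 0.05 ms)."""
        import drgsim as d
        from drgsim.neuron_model import SimConfig

        proto = d.step_family(amplitudes_pA=(75.0,))
        a = d.simulate(wt_params, proto, SimConfig(dt=0.0125, record_dt=0.025))[0]
        b = d.simulate(wt_params, proto, SimConfig(dt=0.0125, record_dt=0.0125))[0]
        fa, fb = sweep_features(a), sweep_features(b)
        assert fb.threshold == pytest.approx(fa.threshold, abs=0.1)
        assert fb.latency == pytest.approx(fa.latency, abs=0.05)
        apa, apb = fa.per_ap[0], fb.per_ap[0]
        assert apb.rise_time_10_90 == pytest.approx(apa.rise_time_10_90, abs=0.05)
        assert apb.duration_at_plus15 == pytest.approx(apa.duration_at_plus15, abs=0.05)
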