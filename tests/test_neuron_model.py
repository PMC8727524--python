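"""Simulator: analytic RC limits, presets, drugs, determinism, convergence."""

import math

import numpy as np
import pytest

import drgsim as d
from drgsim.neuron_model import (
    ChannelSpec,
    IntegrationError,
    NeuronParams,
    SimConfig,
    apply_drug,
    default_params,
    make_genotype,
    resting_state,
    simulate,
)
from drgsim.passive_props import input_resistance, sag_metrics

from conftest import passive_cell


class TestPassiveLimits:
    def test_resting_potential_equals_leak_reversal(self):
        sw = d.simulate(passive_cell(e_leak=-65.0), d.rin_pulse())[0]
        baseline = sw.v[sw.t < sw.onset_ms]
        assert baseline == pytest.approx(-65.0, abs=1e-6)

    def test_ohms_law_steady_state(self):
        # g = 10 nS, I = -50 pA -> steady deflection -5 mV
        sw = d.simulate(passive_cell(g_leak=10.0), d.rin_pulse())[0]
        end = sw.meta["stim_end_ms"]
        steady = sw.v[(sw.t > end - 50) & (sw.t < end)].mean()
        assert steady - (-65.0) == pytest.approx(-5.0, abs=1e-3)

    def test_membrane_time_constant(self):
        """Step response is monoexponential with tau = cm/g_L (2%)."""
        cm, g = 25.0, 2.0
        sw = d.simulate(passive_cell(g_leak=g, cm=cm), d.rin_pulse())[0]
        on = sw.onset_ms
        m = (sw.t >= on) & (sw.t <= on + 60.0)
        t = sw.t[m] - on
        v = sw.v[m]
        v_inf = sw.v[(sw.t > on + 400) & (sw.t < on + 500)].mean()
        # linear fit of log deflection
        y = np.log(np.abs(v - v_inf))
        slope = np.polyfit(t, y, 1)[0]
        tau_fit = -1.0 / slope
        assert tau_fit == pytest.approx(cm / g, rel=0.02)

    def test_rin_independent_of_amplitude(self):
        """Passive Rin identical (1%) for pulses between -10 and -100 pA."""
        rins = []
        for amp in (-10.0, -50.0, -100.0):
            sw = d.simulate(passive_cell(g_leak=5.0), d.rin_pulse(amplitude_pA=amp))[0]
            rins.append(input_resistance(sw))
        assert max(rins) / min(rins) < 1.01
        assert rins[1] == pytest.approx(200.0, rel=0.01)


class TestPresetsAndDrugs:
    def test_zero_cv_gives_exact_defaults(self):
        assert make_genotype("WT", 0.0, seed=7) == default_params("WT")

    def test_ko_differs_only_in_hcn(self):
        wt, ko = default_params("WT"), default_params("KO")
        assert ko.channel("hcn").gbar == pytest.approx(0.4 * wt.channel("hcn").gbar)
        for name in ("leak", "na", "kdr", "km"):
            assert ko.channel(name) == wt.channel(name)
        assert ko.cm == wt.cm

    def test_seeded_variability_is_deterministic(self):
        a = make_genotype("WT", 0.2, seed=1)
        b = make_genotype("WT", 0.2, seed=1)
        assert a == b
        c = make_genotype("WT", 0.2, seed=2)
        assert a != c

    def test_variability_has_unit_mean(self):
        draws = [make_genotype("WT", 0.2, seed=s).channel("hcn").gbar for s in range(300)]
        wt = default_params("WT").channel("hcn").gbar
        assert np.mean(draws) / wt == pytest.approx(1.0, abs=0.05)

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError, match="genotype"):
            make_genotype("HET")

    def test_zd7288_zeroes_hcn_only(self):
        wt = default_params("WT")
        blocked = apply_drug(wt, "ZD7288")
        assert blocked.channel("hcn").gbar == 0.0
        assert blocked.drug == "ZD7288"
        assert blocked.channel("na") == wt.channel("na")

    def test_zd7288_erases_genotype_contrast(self):
        a = apply_drug(default_params("WT"), "ZD7288")
        b = apply_drug(default_params("KO"), "ZD7288")
        assert a.channels == b.channels

    def test_xe991_zeroes_km_not_hcn(self):
        wt = default_params("WT")
        blocked = apply_drug(wt, "XE991")
        assert blocked.channel("km").gbar == 0.0
        assert blocked.channel("hcn").gbar == wt.channel("hcn").gbar

    def test_unknown_drug_rejected(self):
        with pytest.raises(ValueError, match="drug"):
            apply_drug(default_params("WT"), "TTX")


class TestIntegration:
    def test_settles_to_fixed_point(self, wt_params):
        v_rest, residual = resting_state(wt_params)
        assert residual < 0.01  # mV/ms
        assert -61.0 < v_rest < -59.0

    def test_rmp_matches_between_genotypes(self, wt_params, ko_params):
        v_wt, _ = resting_state(wt_params)
        v_ko, _ = resting_state(ko_params)
        assert abs(v_wt - v_ko) < 1.0

    def test_bit_identical_repeat(self, wt_params):
        a = d.simulate(wt_params, d.rin_pulse())[0]
        b = d.simulate(wt_params, d.rin_pulse())[0]
        assert np.array_equal(a.v, b.v)

    def test_fine_timestep_reference(self, wt_params):
        """dt = 0.025 ms trace within 0.5 mV of a 0.0025 ms reference,
        away from AP upstrokes."""
        proto = d.step_family(amplitudes_pA=(100.0,))
        coarse = d.simulate(wt_params, proto, SimConfig(dt=0.025))[0]
        fine = d.simulate(wt_params, proto, SimConfig(dt=0.0025, record_dt=0.025))[0]
        dv = np.abs(np.gradient(fine.v, fine.t))
        calm = dv < 5.0  # exclude upstrokes/downstrokes where phase shifts dominate
        # also drop the 1 ms around every fast segment
        calm = np.convolve(calm, np.ones(81), mode="same") >= 81
        assert np.max(np.abs(coarse.v - fine.v)[calm]) < 0.5

    def test_sag_polarity(self, wt_params, wt_sag_sweeps):
        amp, _ = sag_metrics(wt_sag_sweeps[0])
        assert amp > 0.5
        blocked = apply_drug(wt_params, "ZD7288")
        sw = d.simulate(blocked, d.sag_family(amplitudes_pA=(-50.0,)))[0]
        amp0, _ = sag_metrics(sw)
        assert abs(amp0) < 0.2

    def test_integration_failure_reports_sweep_and_time(self):
        bad = NeuronParams(
            cm=25.0,
            channels=(ChannelSpec("leak", math.inf, -65.0),
                      ChannelSpec("hcn", 0.0, -60.0)),
        )
        with pytest.raises(IntegrationError, match="settling|sweep"):
            simulate(bad, d.rin_pulse())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="record_dt"):
            SimConfig(dt=0.025, record_dt=0.03).validate()
        with pytest.raises(ValueError, match="settle"):
            SimConfig(settle_time=100.0).validate()
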