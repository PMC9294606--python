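"""Spike detection, AP waveform features and excitability metrics."""

import numpy as np
import pytest

from stpkit.aps import (
    ap_features,
    detect_spikes,
    evoked_firing_metrics,
    input_resistance,
    spontaneous_rate,
)
from stpkit.errors import ParameterError
from stpkit.signal_core import StimulusProtocol, Trace
from stpkit.synth import (
    APTemplateSpec,
    first_spike_latency_ms,
    gen_ap_sweeps,
    make_ap_template,
)


class TestDetectSpikes:
    def test_template_train_detected_at_peaks(self):
        sweeps, truth = gen_ap_sweeps(APTemplateSpec(), spont_rate=30.0,
                                      duration=0.2, seed=0)
        spikes = detect_spikes(sweeps.sweeps[0])
        assert spikes.size == 6
        assert np.all(np.abs(spikes - truth.event_times) <= 1 / 50_000.0)

    def test_subthreshold_trace_is_empty(self):
        t = np.linspace(0, 1, 50_000)
        v = -60.0 + 5.0 * np.sin(2 * np.pi * 3 * t)
        assert detect_spikes(Trace(v, 50_000.0, kind="voltage")).size == 0

    def test_count_matches_scheduler_ground_truth(self):
        sweeps, truth = gen_ap_sweeps(APTemplateSpec(), spont_rate=42.0,
                                      duration=1.5, seed=0)
        assert detect_spikes(sweeps.sweeps[0]).size == truth.event_times.size

    def test_dc_offset_invariance(self):
        sweeps, _ = gen_ap_sweeps(APTemplateSpec(), spont_rate=20.0,
                                  duration=0.5, seed=0)
        v = sweeps.sweeps[0]
        shifted = Trace(v.samples - 5.0, v.sampling_rate, kind="voltage")
        n0 = detect_spikes(v, min_peak=-20.0).size
        n1 = detect_spikes(shifted, min_peak=-25.0).size
        assert n0 == n1

    def test_current_trace_rejected(self):
        with pytest.raises(ParameterError):
            detect_spikes(Trace(np.zeros(100), kind="current"))


class TestAPFeatures:
    def test_construction_amplitude_exact(self):
        spec = APTemplateSpec(threshold=-40.0, amplitude=80.0)
        tpl = make_ap_template(spec)
        f = ap_features(tpl, detect_spikes(tpl)[0])
        assert f.amplitude == pytest.approx(80.0, abs=1e-9)
        assert f.threshold == pytest.approx(-40.0, abs=1e-9)

    def test_wild_type_evoked_half_width_recovered(self):
        # half-width 0.31 ms with fast slopes, as for evoked spikes
        spec = APTemplateSpec(half_width=0.31, max_rise=450.0, max_fall=350.0,
                              ahp=15.5)
        tpl = make_ap_template(spec)
        f = ap_features(tpl, detect_spikes(tpl)[0])
        assert f.half_width == pytest.approx(0.31, abs=0.01)

    def test_max_fall_within_2pct(self):
        spec = APTemplateSpec(half_width=0.6, max_fall=189.7, max_rise=300.0)
        tpl = make_ap_template(spec)
        f = ap_features(tpl, detect_spikes(tpl)[0])
        assert f.max_fall == pytest.approx(189.7, rel=0.02)

    @pytest.mark.parametrize("seed", range(6))
    def test_randomized_template_grid_recovery(self, seed):
        rng = np.random.default_rng(seed)
        amplitude = rng.uniform(60.0, 95.0)
        max_rise = rng.uniform(150.0, 320.0)
        max_fall = rng.uniform(120.0, 250.0)
        hw_min = amplitude / 2 * (1 / max_rise + 1 / max_fall)
        spec = APTemplateSpec(
            threshold=rng.uniform(-50.0, -38.0),
            amplitude=amplitude,
            half_width=rng.uniform(1.35, 2.2) * hw_min,
            max_rise=max_rise,
            max_fall=max_fall,
            ahp=rng.uniform(8.0, 22.0),
        )
        tpl = make_ap_template(spec)
        f = ap_features(tpl, detect_spikes(tpl)[0])
        dt_ms = 1e3 / 50_000.0
        assert f.threshold == pytest.approx(spec.threshold, abs=1e-9)
        assert f.amplitude == pytest.approx(spec.amplitude, abs=1e-9)
        assert f.ahp == pytest.approx(spec.ahp, abs=1e-9)
        assert f.half_width == pytest.approx(spec.half_width, abs=dt_ms)
        assert f.max_rise == pytest.approx(spec.max_rise, rel=0.02)
        assert f.max_fall == pytest.approx(spec.max_fall, rel=0.02)


class TestEvokedFiring:
    def test_rate_is_count_over_duration(self):
        step = StimulusProtocol.current_step(onset=0.1, duration=0.2,
                                             amplitude=120.0,
                                             baseline_potential=-60.0)
        sweeps, truth = gen_ap_sweeps(APTemplateSpec(), step_protocol=step, seed=0)
        rate, latency, count = evoked_firing_metrics(sweeps.sweeps[0], step)
        assert count == truth.event_times.size
        assert rate == pytest.approx(count / 0.2)

    def test_latency_matches_closed_form_within_one_sample(self):
        step = StimulusProtocol.current_step(onset=0.1, duration=0.2,
                                             amplitude=50.0,
                                             baseline_potential=-60.0)
        spec = APTemplateSpec()
        sweeps, truth = gen_ap_sweeps(spec, step_protocol=step, seed=0,
                                      tau_m_ms=20.0, r_m_mohm=350.0)
        lat_cf = first_spike_latency_ms(spec.threshold + 60.0, 50.0, 350.0, 20.0)
        _, latency, _ = evoked_firing_metrics(sweeps.sweeps[0], step)
        assert truth.latency_ms == pytest.approx(lat_cf)
        assert abs(latency - lat_cf) <= 1e3 / 50_000.0

    def test_no_spike_sweep_returns_sentinel(self):
        step = StimulusProtocol.current_step(amplitude=5.0,
                                             baseline_potential=-60.0)
        sweeps, _ = gen_ap_sweeps(APTemplateSpec(), step_protocol=step, seed=0)
        rate, latency, count = evoked_firing_metrics(sweeps.sweeps[0], step)
        assert (rate, count) == (0.0, 0)
        assert np.isnan(latency)

    def test_missing_step_definition_rejected(self):
        sweeps, _ = gen_ap_sweeps(APTemplateSpec(), spont_rate=10.0,
                                  duration=0.3, seed=0)
        with pytest.raises(ParameterError):
            evoked_firing_metrics(sweeps.sweeps[0], StimulusProtocol())


class TestRatesAndResistance:
    def test_spontaneous_rate_from_spike_times(self):
        assert spontaneous_rate(np.linspace(0, 0.98, 50), 1.0) == 50.0
        assert spontaneous_rate(np.array([]), 2.0) == 0.0

    def test_spontaneous_rate_from_trace(self):
        sweeps, _ = gen_ap_sweeps(APTemplateSpec(), spont_rate=35.6,
                                  duration=10.0, seed=0)
        assert spontaneous_rate(sweeps.sweeps[0]) == pytest.approx(35.6, abs=0.1)

    def test_ohms_law_single_step(self):
        assert input_resistance([(-100.0, -10.0)]) == pytest.approx(100.0)

    def test_collinear_points_exact(self):
        steps = [(-50.0, -7.5), (-100.0, -15.0)]
        assert input_resistance(steps) == pytest.approx(150.0)

    def test_noisy_steps_match_brute_force_ols(self, rng):
        di = np.array([-150.0, -100.0, -50.0, 50.0, 100.0])
        dv = 0.12 * di + rng.normal(0, 0.5, di.size)
        # textbook OLS including the origin
        x = np.concatenate([[0.0], di])
        y = np.concatenate([[0.0], dv])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert input_resistance(np.c_[di, dv]) == pytest.approx(slope * 1e3,
                                                                abs=1e-12)

    def test_all_zero_current_rejected(self):
        with pytest.raises(ParameterError):
            input_resistance([(0.0, 1.0)])
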