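"""Peak picking, tube-delay correction, and peak-to-trough amplitudes."""

import dataclasses

import numpy as np
import pytest

from sabr import (
    InvalidParameterError,
    NoiseModel,
    correct_latency,
    make_template,
    measure_amplitudes,
    pick_peaks,
    preprocess_pipeline,
    simulate_epochs,
)
from sabr.preprocess import AveragedResponse
from sabr.synth import PEAK_ORDER


def _expected(template):
    return {lab: p.latency_ms for lab, p in template.peak_params.items()}


def _flat_response(n=2000, fs=20_000.0, pre=10.0):
    return AveragedResponse(
        samples=np.zeros(n), sample_rate_hz=fs, pre_stim_ms=pre, n_epochs_used={}
    )


def _bandlimited_truth(template, epochs):
    """Extrema of the band-limited rendered template: the picker's input."""
    from sabr import demean, filter_response

    rendered = template.render(epochs.n_samples, epochs.sample_rate_hz, epochs.pre_stim_ms)
    filt = demean(filter_response(rendered, 70.0, 2000.0, epochs.sample_rate_hz))
    times = (
        np.arange(epochs.n_samples) / epochs.sample_rate_hz * 1000.0 - epochs.pre_stim_ms
    )
    truth = {}
    for lab, p in template.peak_params.items():
        sgn = 1 if lab == "V" else -1
        win = np.abs(times - p.latency_ms) <= 2.0
        idx = np.flatnonzero(win)[np.argmax(sgn * filt[win])]
        truth[lab] = times[idx]
    return truth


class TestPickPeaks:
    def test_recovers_template_latencies_within_one_sample(self, clean_epochs, quiet_template):
        avg = preprocess_pipeline(clean_epochs)
        picked = pick_peaks(avg, _expected(quiet_template))
        truth = _bandlimited_truth(quiet_template, clean_epochs)
        dt = 1000.0 / avg.sample_rate_hz
        for lab, p in quiet_template.peak_params.items():
            assert picked[lab].detected
            assert abs(picked[lab].latency_ms_raw - truth[lab]) <= dt + 1e-9
            # and close to the configured latency itself
            assert abs(picked[lab].latency_ms_raw - p.latency_ms) <= 0.2

    def test_recovers_long_template_including_ffr_coupled_o(self):
        tpl = make_template("long170")
        ep = simulate_epochs(tpl, 16, NoiseModel(sd_uV=0.01), seed=31)
        avg = preprocess_pipeline(ep)
        picked = pick_peaks(avg, _expected(tpl))
        dt = 1000.0 / avg.sample_rate_hz
        assert picked["O"].detected
        assert abs(picked["O"].latency_ms_raw - 72.0) <= dt + 1e-9

    def test_flat_waveform_assigns_nothing(self, quiet_template):
        picked = pick_peaks(_flat_response(), _expected(quiet_template))
        assert picked.labels_detected() == frozenset()

    def test_correct_sign_required_for_assignment(self):
        """A negative trough in V's window must not be assigned to V."""
        avg = _flat_response()
        t = avg.times_ms
        avg.samples = -0.3 * np.exp(-0.5 * ((t - 6.6) / 0.5) ** 2)
        picked = pick_peaks(avg, {"V": 6.6}, half_window_ms=2.0)
        assert not picked["V"].detected

    def test_nonmonotone_expected_latencies_rejected(self, quiet_template):
        exp = _expected(quiet_template)
        exp["A"] = exp["V"] - 1.0
        with pytest.raises(InvalidParameterError):
            pick_peaks(_flat_response(), exp)

    def test_latency_shift_equivariance(self, quiet_template):
        """Shifting the whole template by delta shifts every pick by delta."""
        delta = 0.91
        shifted = make_template(
            "short50",
            overrides={
                lab: dataclasses.replace(p, latency_ms=p.latency_ms + delta)
                for lab, p in quiet_template.peak_params.items()
            },
        )
        base = simulate_epochs(quiet_template, 8, NoiseModel(sd_uV=0.0), seed=1)
        moved = simulate_epochs(shifted, 8, NoiseModel(sd_uV=0.0), seed=1)
        avg_b = preprocess_pipeline(base)
        avg_m = preprocess_pipeline(moved)
        picked_b = pick_peaks(avg_b, _expected(quiet_template))
        picked_m = pick_peaks(avg_m, _expected(shifted))
        dt = 1000.0 / avg_b.sample_rate_hz
        for lab in PEAK_ORDER:
            d = picked_m[lab].latency_ms_raw - picked_b[lab].latency_ms_raw
            assert abs(d - delta) <= dt + 1e-9

    def test_background_effect_recovered_within_tolerance(self):
        """Quiet-vs-noise latency differences reproduce the configured shift
        (+0.91 ms) within +/-0.2 ms at low noise."""
        shift = make_template("short50", "noise").background_effect[0]
        q = simulate_epochs(make_template("short50", "quiet"), 64,
                            NoiseModel(sd_uV=0.02), seed=61)
        n = simulate_epochs(make_template("short50", "noise"), 64,
                            NoiseModel(sd_uV=0.02), seed=62)
        avg_q, avg_n = preprocess_pipeline(q), preprocess_pipeline(n)
        picked_q = pick_peaks(avg_q, _expected(make_template("short50", "quiet")))
        picked_n = pick_peaks(avg_n, _expected(make_template("short50", "noise")))
        diffs = [
            picked_n[lab].latency_ms_raw - picked_q[lab].latency_ms_raw
            for lab in PEAK_ORDER
        ]
        assert np.all(np.abs(np.asarray(diffs) - shift) <= 0.2)


class TestCorrectLatency:
    def test_constant_shift(self):
        assert correct_latency(6.69) == pytest.approx(5.89)
        assert correct_latency(0.8) == 0.0

    def test_elementwise_on_vectors(self):
        np.testing.assert_allclose(
            correct_latency(np.array([6.6, 7.9])), [5.8, 7.1]
        )

    def test_below_tube_delay_rejected(self):
        with pytest.raises(InvalidParameterError):
            correct_latency(0.5)

    def test_pure_shift_leaves_amplitudes_untouched(self, clean_epochs, quiet_template):
        avg = preprocess_pipeline(clean_epochs)
        picked = measure_amplitudes(avg, pick_peaks(avg, _expected(quiet_template)))
        for lab in PEAK_ORDER:
            p = picked[lab]
            assert p.latency_ms_corrected == pytest.approx(p.latency_ms_raw - 0.8)
        # amplitudes were computed from sample values only, never latencies
        assert picked["V"].amplitude_uV == pytest.approx(
            picked["V"].value_uV - picked["A"].value_uV
        )


class TestMeasureAmplitudes:
    def _response_with(self, peaks):
        avg = _flat_response()
        t = avg.times_ms
        for mu, amp, sig in peaks:
            avg.samples = avg.samples + amp * np.exp(-0.5 * ((t - mu) / sig) ** 2)
        return avg

    def test_v_to_a_arithmetic(self):
        avg = self._response_with([(6.6, 0.5, 0.4), (8.2, -0.3, 0.4)])
        picked = measure_amplitudes(avg, pick_peaks(avg, {"V": 6.6, "A": 8.2}, 1.0))
        assert picked["V"].amplitude_uV == pytest.approx(0.8, abs=0.02)

    def test_trough_measured_against_preceding_positive_peak(self):
        avg = self._response_with([(19.0, 0.2, 0.8), (22.5, -0.1, 0.8)])
        picked = measure_amplitudes(avg, pick_peaks(avg, {"D": 22.5}, 1.0))
        assert picked["D"].amplitude_uV == pytest.approx(0.3, abs=0.02)

    def test_missing_preceding_positive_peak_flags_amplitude(self):
        avg = self._response_with([(22.5, -0.1, 0.8)])  # nothing positive before
        picked = measure_amplitudes(avg, pick_peaks(avg, {"D": 22.5}, 1.0))
        assert picked["D"].amplitude_uV is None
        assert picked["D"].amplitude_flag is not None

    def test_template_amplitudes_recovered_within_10_percent(self, clean_epochs, quiet_template):
        """The measurement rules recover configured peak-to-trough values on
        the unfiltered rendered template (generator ground truth)."""
        rendered = quiet_template.render(
            clean_epochs.n_samples, clean_epochs.sample_rate_hz, clean_epochs.pre_stim_ms
        )
        avg = AveragedResponse(
            samples=rendered - rendered.mean(),
            sample_rate_hz=clean_epochs.sample_rate_hz,
            pre_stim_ms=clean_epochs.pre_stim_ms,
            n_epochs_used={},
        )
        picked = measure_amplitudes(avg, pick_peaks(avg, _expected(quiet_template)))
        for lab, expected in quiet_template.expected_peak_to_trough().items():
            assert picked[lab].amplitude_uV == pytest.approx(expected, rel=0.10)

    def test_noise_condition_shrinks_amplitudes(self):
        """Synthetic responses in background noise have smaller peak-to-trough
        amplitudes than in quiet (generator contrast survives the pipeline)."""
        q = simulate_epochs(make_template("short50", "quiet"), 32,
                            NoiseModel(sd_uV=0.1), seed=91)
        n = simulate_epochs(make_template("short50", "noise"), 32,
                            NoiseModel(sd_uV=0.1), seed=92)
        avg_q, avg_n = preprocess_pipeline(q), preprocess_pipeline(n)
        pq = measure_amplitudes(avg_q, pick_peaks(avg_q, _expected(make_template("short50"))))
        pn = measure_amplitudes(avg_n, pick_peaks(avg_n, _expected(make_template("short50", "noise"))))
        for lab in PEAK_ORDER:
            if pq[lab].amplitude_uV is not None and pn[lab].amplitude_uV is not None:
                assert pn[lab].amplitude_uV < pq[lab].amplitude_uV
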