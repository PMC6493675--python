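"""Stimulus synthesis, response templates, and epoch simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sabr import (
    InvalidParameterError,
    NoiseModel,
    PeakShape,
    StimulusSpec,
    clip_stimulus,
    cv_spec,
    make_template,
    simulate_epochs,
    synthesize_cv,
)
from sabr.synth import DEFAULT_BACKGROUND_EFFECT, DEFAULT_PEAKS


class TestSynthesizeCV:
    def test_length_is_duration_times_rate(self):
        stim = synthesize_cv(cv_spec("da", 170.0))
        assert stim.waveform.size == 3400

    def test_inverted_polarity_is_samplewise_negation(self):
        orig = synthesize_cv(cv_spec("ba", 50.0))
        inv = synthesize_cv(cv_spec("ba", 50.0, polarity="inverted"))
        np.testing.assert_array_equal(inv.waveform, -orig.waveform)

    def test_autocorrelation_peak_at_f0_period(self):
        # constant formants, no burst: exactly periodic at 1/f0 = 10 ms
        spec = StimulusSpec(
            duration_ms=200.0,
            f0_hz=100.0,
            formant_tracks=((700.0, 700.0, 0.0), (1200.0, 1200.0, 0.0)),
            onset_burst_ms=0.0,
        )
        x = synthesize_cv(spec).waveform
        ac = np.correlate(x, x, "full")[x.size - 1 :]
        lag = np.argmax(ac[100:300]) + 100
        assert lag == 200  # 10 ms at 20 kHz

    def test_formant_above_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError, match="Nyquist"):
            StimulusSpec(duration_ms=50.0, formant_tracks=((12_000.0, 12_000.0, 0.0),))

    def test_spectral_peaks_cover_f0_and_formant_targets(self):
        """Harmonic-envelope humps sit at F0 and each formant endpoint."""
        stim = synthesize_cv(cv_spec("da", 170.0))
        fs = stim.sample_rate_hz
        steady = stim.waveform[-1600:]  # last 80 ms: transitions done
        spec = np.abs(np.fft.rfft(steady * np.hanning(steady.size)))
        freqs = np.fft.rfftfreq(steady.size, 1.0 / fs)
        f0 = stim.spec.f0_hz

        def harmonic_mag(f_target):
            k = round(f_target / f0)
            return spec[np.argmin(np.abs(freqs - k * f0))]

        targets = [f0] + [end for (_s, end, _t) in stim.spec.formant_tracks]
        for f_target in targets:
            # envelope hump: stronger than the harmonic 3 steps toward the gap
            here = harmonic_mag(f_target)
            if f_target == f0:
                assert here > harmonic_mag(f_target + 3 * f0)
            else:
                assert here > harmonic_mag(f_target - 3 * f0)

    def test_f2_differs_across_cvs(self):
        tracks = {cv: cv_spec(cv, 50.0).formant_tracks[1] for cv in ("ba", "da", "ga")}
        starts = {cv: t[0] for cv, t in tracks.items()}
        assert starts["ba"] < starts["da"] < starts["ga"]
        assert len({t[1] for t in tracks.values()}) == 1  # shared vowel target


class TestClipStimulus:
    def test_first_40_ms_unaltered_and_terminal_gain_reduced(self):
        spec = StimulusSpec(duration_ms=170.0, onset_burst_ms=0.0,
                            formant_tracks=((700.0, 700.0, 0.0),))
        stim = synthesize_cv(spec)
        stim.waveform[:] = 1.0  # constant probe isolates the window gain
        out = clip_stimulus(stim, 50.0, 10.0)
        assert out.waveform.size == 1000
        np.testing.assert_array_equal(out.waveform[:800], 1.0)
        assert abs(out.waveform[-1]) <= 0.1  # >90% amplitude reduction

    def test_full_duration_zero_ramp_is_identity(self):
        stim = synthesize_cv(cv_spec("ga", 50.0))
        out = clip_stimulus(stim, 50.0, 0.0)
        np.testing.assert_array_equal(out.waveform, stim.waveform)

    def test_keep_longer_than_duration_rejected(self):
        stim = synthesize_cv(cv_spec("da", 50.0))
        with pytest.raises(InvalidParameterError):
            clip_stimulus(stim, 60.0, 10.0)


class TestMakeTemplate:
    def test_short_templates_have_no_ffr_and_terminal_o(self):
        for cls in ("short40", "short50"):
            tpl = make_template(cls)
            assert tpl.ffr is None
            lats = [p.latency_ms for p in tpl.peak_params.values()]
            assert tpl.peak_params["O"].latency_ms == max(lats)

    def test_long_template_ffr_spans_sustained_period(self):
        tpl = make_template("long170")
        assert tpl.ffr is not None
        assert tpl.ffr.start_ms <= 70.0 and tpl.ffr.end_ms >= 170.0

    def test_noise_condition_shifts_every_latency_by_configured_amount(self):
        quiet = make_template("short50", "quiet")
        noise = make_template("short50", "noise")
        shift, scale = DEFAULT_BACKGROUND_EFFECT
        for lab in quiet.peak_params:
            dq, dn = quiet.peak_params[lab], noise.peak_params[lab]
            assert dn.latency_ms == pytest.approx(dq.latency_ms + shift)
            assert dn.amplitude_uV == pytest.approx(dq.amplitude_uV * scale)

    def test_order_violating_override_rejected(self):
        with pytest.raises(InvalidParameterError, match="increasing"):
            make_template("short50", overrides={"A": PeakShape(5.0, 0.25, 1.0, -1)})

    def test_positive_a_rejected(self):
        with pytest.raises(InvalidParameterError, match="negative"):
            make_template("short50", overrides={"A": PeakShape(7.9, 0.25, 1.0, +1)})


class TestSimulateEpochs:
    def test_noiseless_limit_reproduces_template(self, quiet_template):
        ep = simulate_epochs(quiet_template, 4, NoiseModel(sd_uV=0.0), seed=1)
        rendered = quiet_template.render(ep.n_samples, ep.sample_rate_hz, ep.pre_stim_ms)
        for j in range(4):
            np.testing.assert_allclose(ep.data[:, j], rendered, atol=1e-12)

    def test_same_seed_bitwise_identical(self, quiet_template):
        kw = dict(n_epochs=32, noise=NoiseModel(sd_uV=2.5, artifact_rate=0.1), seed=42)
        a = simulate_epochs(quiet_template, **kw)
        b = simulate_epochs(quiet_template, **kw)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.polarity, b.polarity)

    def test_artifact_count_matches_binomial_rate(self, quiet_template):
        n, rate = 4000, 0.05
        ep = simulate_epochs(
            quiet_template, n, NoiseModel(sd_uV=2.5, artifact_rate=rate), seed=7
        )
        count = int(np.sum(np.max(np.abs(ep.data), axis=0) > 20.0))
        # 4 sigma binomial tolerance around the expected 200
        sigma = np.sqrt(n * rate * (1 - rate))
        assert abs(count - n * rate) < 4 * sigma

    def test_no_sound_condition_and_polarity_balance(self):
        ep = simulate_epochs(None, 101, NoiseModel(sd_uV=1.0), seed=3)
        assert ep.condition == "no_sound"
        counts = np.bincount(ep.polarity, minlength=2)
        assert abs(int(counts[0]) - int(counts[1])) <= 1

    def test_fewer_than_two_epochs_rejected(self, quiet_template):
        with pytest.raises(InvalidParameterError):
            simulate_epochs(quiet_template, 1, NoiseModel(), seed=1)

    def test_polarity_artifact_cancels_in_alternating_mean(self, quiet_template):
        """The stimulus-following component inverts with polarity: the mean of
        the two single-polarity averages equals the evoked template, while each
        single-polarity average does not."""
        ep = simulate_epochs(
            quiet_template, 8, NoiseModel(sd_uV=0.0, cm_artifact_uV=0.5), seed=5
        )
        rendered = quiet_template.render(ep.n_samples, ep.sample_rate_hz, ep.pre_stim_ms)
        avg0 = ep.data[:, ep.polarity == 0].mean(axis=1)
        avg1 = ep.data[:, ep.polarity == 1].mean(axis=1)
        np.testing.assert_allclose(0.5 * (avg0 + avg1), rendered, atol=1e-10)
        assert np.max(np.abs(avg0 - rendered)) > 0.1
        assert np.max(np.abs(avg1 - rendered)) > 0.1


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    amp=st.floats(min_value=21.0, max_value=200.0),
    rate=st.floats(min_value=0.0, max_value=1.0),
)
def test_noise_model_invariants_accept_valid_parameters(amp, rate):
    model = NoiseModel(sd_uV=1.0, artifact_rate=rate, artifact_amp_uV=amp)
    assert 0.0 <= model.artifact_rate <= 1.0


def test_noise_model_rejects_subthreshold_artifacts():
    with pytest.raises(InvalidParameterError, match="20"):
        NoiseModel(artifact_rate=0.1, artifact_amp_uV=15.0)
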