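"""Filtering, differentiation, sinusoid fitting, and the two-pass exclusion rules."""

import numpy as np
import pytest
import scipy.signal

from conftest import interval_oracle_excluded_fraction
from vorlab import desaccade, synth
from vorlab.desaccade import FilterSpec
from vorlab.synth import EyeTrace, GroundTruth

FS = 1000.0


def make_trace(values, kind="velocity", fs=FS):
    t = np.arange(len(values)) / fs
    return EyeTrace(t, np.asarray(values, dtype=float), kind, fs)


def sine_velocity(amp=8.0, freq=1.0, phase_deg=0.0, offset=0.0, dur=45.0, fs=FS):
    t = np.arange(round(dur * fs)) / fs
    v = offset + amp * np.sin(2 * np.pi * freq * t + np.deg2rad(phase_deg))
    return EyeTrace(t, v, "velocity", fs)


class TestLowpass:
    def test_dc_gain_is_unity(self):
        out = desaccade.lowpass_position(make_trace(np.full(5000, 5.0), "position"))
        np.testing.assert_allclose(out.values[100:-100], 5.0, atol=1e-6)

    def test_passband_1hz_amplitude(self):
        t = np.arange(10_000) / FS
        out = desaccade.lowpass_position(make_trace(np.sin(2 * np.pi * t), "position"))
        assert np.max(np.abs(out.values[1000:-1000])) == pytest.approx(1.0, rel=0.01)

    def test_single_pass_minus_3db_at_cutoff(self):
        """The designed filter is -3 dB at 15 Hz; the zero-phase two-pass
        application squares that to 1/2."""
        spec = FilterSpec()
        w, h = scipy.signal.sosfreqz(spec.sos(FS), worN=[15.0], fs=FS)
        assert abs(h[0]) == pytest.approx(1 / np.sqrt(2), rel=0.01)
        t = np.arange(20_000) / FS
        causal = FilterSpec(zero_phase=False)
        single = desaccade.lowpass_position(
            make_trace(np.sin(2 * np.pi * 15 * t), "position"), causal)
        assert np.max(np.abs(single.values[5000:])) == pytest.approx(1 / np.sqrt(2), rel=0.01)
        double = desaccade.lowpass_position(
            make_trace(np.sin(2 * np.pi * 15 * t), "position"))
        assert np.max(np.abs(double.values[5000:15000])) == pytest.approx(0.5, rel=0.01)

    def test_cutoff_above_nyquist_rejected(self):
        trace = make_trace(np.zeros(1000), "position", fs=25.0)
        with pytest.raises(ValueError):
            desaccade.lowpass_position(trace, FilterSpec(butter_cutoff_hz=15.0))


class TestDifferentiate:
    def test_linear_ramp(self):
        t = np.arange(5000) / FS
        out = desaccade.differentiate(make_trace(3.0 * t, "position"))
        np.testing.assert_allclose(out.values[50:-50], 3.0, atol=1e-9)

    def test_constant_position_gives_zero_velocity(self):
        out = desaccade.differentiate(make_trace(np.full(2000, 7.0), "position"))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_sinusoid_amplitude_within_one_percent(self):
        t = np.arange(45_000) / FS
        pos = make_trace((10 / (2 * np.pi)) * np.sin(2 * np.pi * t), "position")
        v = desaccade.differentiate(pos)
        assert np.max(np.abs(v.values[100:-100])) == pytest.approx(10.0, rel=0.01)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            desaccade.differentiate(make_trace(np.zeros(10), "position"))


class TestFitSinusoid:
    def test_exact_pure_sine(self):
        fit = desaccade.fit_sinusoid(sine_velocity(amp=8.0), 1.0)
        assert fit.amplitude == pytest.approx(8.0, abs=1e-9)
        assert fit.phase_deg == pytest.approx(0.0, abs=1e-7)
        assert fit.offset == pytest.approx(0.0, abs=1e-9)

    def test_exact_with_offset_and_phase(self):
        fit = desaccade.fit_sinusoid(sine_velocity(amp=8.0, phase_deg=60.0, offset=2.0), 1.0)
        assert fit.amplitude == pytest.approx(8.0, abs=1e-9)
        assert fit.phase_deg == pytest.approx(60.0, abs=1e-7)
        assert fit.offset == pytest.approx(2.0, abs=1e-9)

    def test_noisy_fit_matches_nonlinear_oracle(self):
        rng = np.random.default_rng(11)
        v = sine_velocity(amp=8.0, dur=10.0)
        v.values = v.values + rng.normal(0, 2.0, len(v))
        lin = desaccade.fit_sinusoid(v, 1.0)
        nls = desaccade.fit_sinusoid_nls(v, 1.0)
        # SE of the amplitude for a sinusoid in white noise
        se = 2.0 * np.sqrt(2.0 / len(v))
        assert abs(lin.amplitude - 8.0) < 3 * se
        assert lin.amplitude == pytest.approx(nls.amplitude, rel=1e-6)

    def test_oracle_equivalence_on_random_instances(self):
        """Linear-basis fit vs generic nonlinear least squares, 50 instances."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            amp = rng.uniform(0.5, 15)
            ph = rng.uniform(-170, 170)
            off = rng.uniform(-3, 3)
            v = sine_velocity(amp, 1.0, ph, off, dur=rng.uniform(2, 6))
            v.values = v.values + rng.normal(0, rng.uniform(0, 1), len(v))
            lin = desaccade.fit_sinusoid(v, 1.0)
            nls = desaccade.fit_sinusoid_nls(v, 1.0, x0=(amp, 0.0, 0.0))
            assert lin.amplitude == pytest.approx(nls.amplitude, rel=1e-6)

    def test_insufficient_span_rejected(self):
        with pytest.raises(ValueError):
            desaccade.fit_sinusoid(sine_velocity(dur=0.5), 1.0)


class TestExclusionMask:
    def test_clean_trace_excludes_nothing(self):
        v = sine_velocity()
        fit = desaccade.fit_sinusoid(v, 1.0)
        mask = desaccade.build_exclusion_mask(v, fit)
        assert mask.excluded_fraction == 0.0

    def test_single_event_margin_span(self):
        """A 100 ms suprathreshold run at 10 s excludes exactly [9.95, 10.15) s:
        200 ms of 45 s ~ 0.444%."""
        v = sine_velocity()
        v.values[10_000:10_100] += 40.0
        fit_clean = desaccade.SinusoidFit(1.0, 8.0, 0.0, 0.0, len(v), 0.0)
        mask = desaccade.build_exclusion_mask(v, fit_clean)
        idx = np.flatnonzero(mask.excluded)
        assert idx[0] == 9_950 and idx[-1] == 10_149
        assert mask.excluded_fraction == pytest.approx(200.0 / 45_000.0 * FS / FS)
        assert mask.excluded_fraction == 200.0 / 45_000.0

    def test_nearby_events_merge_through_margins(self):
        """Two 100 ms events 180 ms apart: the 50 ms margins overlap the 80 ms
        gap, so one contiguous run is excluded."""
        v = sine_velocity()
        v.values[10_000:10_100] += 40.0
        v.values[10_180:10_280] += 40.0
        fit_clean = desaccade.SinusoidFit(1.0, 8.0, 0.0, 0.0, len(v), 0.0)
        mask = desaccade.build_exclusion_mask(v, fit_clean)
        idx = np.flatnonzero(mask.excluded)
        assert idx[0] == 9_950 and idx[-1] == 10_329
        assert np.all(np.diff(idx) == 1)  # single merged run
        oracle = interval_oracle_excluded_fraction(
            [(10.0, 10.1), (10.18, 10.28)], len(v), FS)
        assert mask.excluded_fraction == oracle

    @pytest.mark.parametrize("spans", [
        [(5.0, 5.1)],
        [(5.0, 5.1), (5.18, 5.28)],                  # margins merge
        [(5.0, 5.1), (5.205, 5.305)],                # 5 ms retained gap -> short segment
        [(1.0, 1.05), (10.0, 10.03), (10.2, 10.26), (44.0, 44.2)],
        [(0.0, 0.08), (44.9, 45.0 - 1e-3)],          # runs touching the trace ends
    ])
    def test_excluded_fraction_matches_interval_oracle(self, spans):
        v = sine_velocity()
        for s, e in spans:
            v.values[round(s * FS):round(e * FS)] += 40.0
        fit_clean = desaccade.SinusoidFit(1.0, 8.0, 0.0, 0.0, len(v), 0.0)
        mask = desaccade.build_exclusion_mask(v, fit_clean)
        oracle = interval_oracle_excluded_fraction(spans, len(v), FS)
        assert mask.excluded_fraction == oracle

    def test_threshold_monotonicity(self):
        """Raising the residual threshold never increases the excluded fraction."""
        rng = np.random.default_rng(23)
        v = sine_velocity(dur=20.0)
        v.values = v.values + rng.normal(0, 15.0, len(v))
        fit = desaccade.fit_sinusoid(v, 1.0)
        fracs = [desaccade.build_exclusion_mask(v, fit, threshold_dps=th).excluded_fraction
                 for th in (5, 10, 20, 31, 45, 80)]
        assert all(a >= b for a, b in zip(fracs[:-1], fracs[1:]))


class TestTwoPassTrial:
    def test_clean_round_trip(self, vor_spec, clean_test):
        res = desaccade.analyze_test(clean_test.eye_position, 1.0)
        assert res.valid
        assert res.amplitude == pytest.approx(8.0, abs=0.01)

    @staticmethod
    def _pulsed_trace(n_events):
        """Evenly spaced, well-separated 100 ms pulses of ±40 deg/s; each
        excludes exactly 200 ms after margins, so the total fraction is
        n_events · 200 ms / 45 s."""
        v = sine_velocity()
        rng = np.random.default_rng(31)
        period = (45.0 - 0.4) / n_events
        for k in range(n_events):
            i0 = round((0.1 + k * period) * FS)
            v.values[i0:i0 + 100] += 40.0 * rng.choice([-1.0, 1.0])
        return v

    def test_forty_six_percent_contamination_invalidates(self):
        res = desaccade.analyze_trial(self._pulsed_trace(104), 1.0)
        assert res.mask.excluded_fraction == 104 * 200.0 / 45_000.0  # 46.2%
        assert not res.valid and res.amplitude is None

    def test_forty_four_percent_contamination_stays_valid(self):
        res = desaccade.analyze_trial(self._pulsed_trace(99), 1.0)
        assert res.mask.excluded_fraction == 99 * 200.0 / 45_000.0   # 44.0%
        assert res.valid
        assert res.amplitude == pytest.approx(8.0, rel=0.02)

    def test_second_pass_beats_first_on_contaminated_traces(self, vor_spec):
        """On saccade-contaminated synthetic tests, the refit on retained data
        is at least as accurate as the first pass in >= 95% of 200 seeds."""
        truth = GroundTruth(gain=0.8, noise_sd_dps=2.0, saccade_rate_hz=1.0)
        better = 0
        for s in range(200):
            rec = synth.synthesize_test(vor_spec, truth, rng=10_000 + s)
            r = desaccade.analyze_test(rec.eye_position, 1.0)
            assert r.valid
            better += abs(r.fit.amplitude - 8.0) <= abs(r.fit_first_pass.amplitude - 8.0)
        assert better / 200 >= 0.95

    def test_trial_record_serializes(self, clean_test):
        rec = desaccade.analyze_test(clean_test.eye_position, 1.0).to_record()
        assert rec["valid"] and "fit" in rec
        assert sum(length for _, length in rec["exclusion_runs"]) == 45_000
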