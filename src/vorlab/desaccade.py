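"""Preprocessing and two-pass desaccade/sinusoid-fit pipeline.

The measurement chain for each 45 s VOR test or 50 s OKR block:

1. low-pass the raw eye-position signal (4th-order Butterworth, 15 Hz);
2. differentiate with a windowed (30 ms) Savitzky–Golay filter to eye velocity;
3. fit a fixed-frequency (1 or 0.5 Hz) sinusoid to the whole velocity trace;
4. mark samples whose residual from that fit exceeds 31 deg/s as
   saccades/artifacts, extend every such run by 50 ms on both sides, and also
   discard retained segments shorter than 10 ms;
5. declare the trial invalid if more than 45% of the data points are excluded;
   otherwise refit the sinusoid on the retained samples only.  The amplitude of
   this second fit is the eye-movement response amplitude.

Exactly two passes are performed; there is no iterative re-thresholding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.signal

from .synth import EyeTrace

__all__ = [
    "FilterSpec",
    "SinusoidFit",
    "ExclusionMask",
    "TrialResult",
    "REASON_RETAINED",
    "REASON_SACCADE",
    "REASON_MARGIN",
    "REASON_SHORT_SEGMENT",
    "REASON_EDGE",
    "lowpass_position",
    "differentiate",
    "preprocess",
    "fit_sinusoid",
    "fit_sinusoid_nls",
    "build_exclusion_mask",
    "analyze_trial",
    "analyze_test",
]

# per-sample reason codes
REASON_RETAINED = 0
REASON_SACCADE = 1        # |residual| > threshold
REASON_MARGIN = 2         # within the dilation margin of a saccade run
REASON_SHORT_SEGMENT = 3  # retained run shorter than the minimum segment
REASON_EDGE = 4           # differentiation half-window at the trace ends


@dataclass(frozen=True)
class FilterSpec:
    """Preprocessing parameters.

    ``zero_phase`` applies the Butterworth forward-backward (filtfilt) so the
    fitted amplitude/phase do not inherit filter lag; set False for a causal
    single pass.  The Savitzky-Golay window is specified in milliseconds and
    converted to the nearest odd sample count.
    """

    butter_order: int = 4
    butter_cutoff_hz: float = 15.0
    savgol_window_ms: float = 30.0
    savgol_polyorder: int = 3
    zero_phase: bool = True

    def savgol_window_samples(self, sample_rate: float) -> int:
        n = int(round(self.savgol_window_ms * 1e-3 * sample_rate))
        if n % 2 == 0:
            n += 1
        if n < self.savgol_polyorder + 2:
            raise ValueError("Savitzky-Golay window too short for the polynomial order")
        return n

    def sos(self, sample_rate: float) -> np.ndarray:
        if self.butter_cutoff_hz >= sample_rate / 2:
            raise ValueError("Butterworth cutoff must be below Nyquist")
        return scipy.signal.butter(self.butter_order, self.butter_cutoff_hz,
                                   btype="low", fs=sample_rate, output="sos")


@dataclass(frozen=True)
class SinusoidFit:
    """Least-squares fit of ``offset + amplitude·sin(2πft + phase)`` at fixed f."""

    freq: float
    amplitude: float
    phase_deg: float
    offset: float
    n_used: int
    rmse: float

    def reconstruct(self, t: np.ndarray) -> np.ndarray:
        return self.offset + self.amplitude * np.sin(
            2 * np.pi * self.freq * t + np.deg2rad(self.phase_deg))


@dataclass
class ExclusionMask:
    """Per-sample exclusion state for one trial.

    ``excluded_fraction`` counts saccade/margin/short-segment exclusions over
    the analyzable samples; the differentiation edge samples are flagged
    separately (``reasons == REASON_EDGE``) and sit outside both numerator and
    denominator of the 45% rule.
    """

    excluded: np.ndarray          # bool, True = not used in the second fit
    reasons: np.ndarray           # int8 reason code per sample
    excluded_fraction: float
    threshold_dps: float
    margin_s: float
    min_segment_s: float

    @property
    def retained(self) -> np.ndarray:
        return ~self.excluded


@dataclass
class TrialResult:
    """Outcome of the two-pass analysis of one test."""

    fit_first_pass: SinusoidFit
    mask: ExclusionMask
    valid: bool
    fit: SinusoidFit | None = None  # second pass; None when invalid

    @property
    def amplitude(self) -> float | None:
        return None if self.fit is None else self.fit.amplitude

    def to_record(self) -> dict:
        rec = {
            "valid": self.valid,
            "excluded_fraction": self.mask.excluded_fraction,
            "first_pass": {
                "amplitude": self.fit_first_pass.amplitude,
                "phase_deg": self.fit_first_pass.phase_deg,
                "offset": self.fit_first_pass.offset,
                "rmse": self.fit_first_pass.rmse,
            },
            "exclusion_runs": _run_length_codes(self.mask.reasons),
        }
        if self.fit is not None:
            rec["fit"] = {
                "freq": self.fit.freq,
                "amplitude": self.fit.amplitude,
                "phase_deg": self.fit.phase_deg,
                "offset": self.fit.offset,
                "n_used": self.fit.n_used,
                "rmse": self.fit.rmse,
            }
        return rec


def _run_length_codes(reasons: np.ndarray) -> list[list[int]]:
    """Run-length encode the reason codes: [[code, length], ...]."""
    out: list[list[int]] = []
    for code in reasons:
        c = int(code)
        if out and out[-1][0] == c:
            out[-1][1] += 1
        else:
            out.append([c, 1])
    return out


def lowpass_position(trace: EyeTrace, spec: FilterSpec = FilterSpec()) -> EyeTrace:
    """Low-pass the eye-position trace (4th-order Butterworth, 15 Hz).

    Zero-phase by default; the single-pass magnitude response of the designed
    filter (-3 dB at cutoff) is a property of ``spec.sos`` regardless.
    """
    if trace.kind != "position":
        raise ValueError("lowpass_position expects a position trace")
    if trace.sample_rate <= 2 * spec.butter_cutoff_hz:
        raise ValueError("sample rate must exceed twice the filter cutoff")
    sos = spec.sos(trace.sample_rate)
    if spec.zero_phase:
        y = scipy.signal.sosfiltfilt(sos, trace.values)
    else:
        y = scipy.signal.sosfilt(sos, trace.values)
    return EyeTrace(trace.t, y, "position", trace.sample_rate)


def differentiate(trace: EyeTrace, spec: FilterSpec = FilterSpec()) -> EyeTrace:
    """Savitzky-Golay differentiation of position (deg) to velocity (deg/s)."""
    if trace.kind != "position":
        raise ValueError("differentiate expects a position trace")
    win = spec.savgol_window_samples(trace.sample_rate)
    if len(trace) < win:
        raise ValueError("trace shorter than the differentiation window")
    v = scipy.signal.savgol_filter(trace.values, win, spec.savgol_polyorder,
                                   deriv=1, delta=1.0 / trace.sample_rate)
    return EyeTrace(trace.t, v, "velocity", trace.sample_rate)


def preprocess(trace: EyeTrace, spec: FilterSpec = FilterSpec()) -> tuple[EyeTrace, int]:
    """Filter + differentiate; returns (velocity, edge half-window in samples)."""
    v = differentiate(lowpass_position(trace, spec), spec)
    return v, spec.savgol_window_samples(trace.sample_rate) // 2


def fit_sinusoid(v: EyeTrace, freq: float,
                 include: np.ndarray | None = None) -> SinusoidFit:
    """Linear least-squares fit of a fixed-frequency sinusoid.

    Solves ``v ≈ offset + a·sin(2πft) + b·cos(2πft)`` on the included samples;
    amplitude = √(a²+b²), phase = atan2(b, a).  Requires at least three
    included samples spanning at least one stimulus cycle.
    """
    if v.kind != "velocity":
        raise ValueError("fit_sinusoid expects a velocity trace")
    if include is None:
        include = np.ones(len(v), dtype=bool)
    t = v.t[include]
    y = v.values[include]
    if len(t) < 3 or (t.max() - t.min()) < 1.0 / freq:
        raise ValueError("need >= 3 samples spanning at least one stimulus cycle")
    w = 2 * np.pi * freq
    X = np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    offset, a, b = beta
    amplitude = float(np.hypot(a, b))
    phase = float(np.rad2deg(math.atan2(b, a)))
    if phase <= -180.0:
        phase += 360.0
    resid = y - X @ beta
    return SinusoidFit(freq=freq, amplitude=amplitude, phase_deg=phase,
                       offset=float(offset), n_used=int(len(t)),
                       rmse=float(np.sqrt(np.mean(resid ** 2))))


def fit_sinusoid_nls(v: EyeTrace, freq: float,
                     include: np.ndarray | None = None,
                     x0: tuple[float, float, float] = (1.0, 0.0, 0.0)) -> SinusoidFit:
    """Brute-force nonlinear least squares over (amplitude, phase, offset).

    Independent cross-check of :func:`fit_sinusoid`; same model, generic
    optimizer instead of the linear-basis solution.
    """
    if include is None:
        include = np.ones(len(v), dtype=bool)
    t = v.t[include]
    y = v.values[include]
    w = 2 * np.pi * freq

    def resid(p):
        amp, phase, off = p
        return off + amp * np.sin(w * t + phase) - y

    sol = scipy.optimize.least_squares(resid, x0=np.asarray(x0), method="lm")
    amp, phase, off = sol.x
    if amp < 0:
        amp, phase = -amp, phase + np.pi
    phase_deg = (np.rad2deg(phase) + 180.0) % 360.0 - 180.0
    if phase_deg <= -180.0:
        phase_deg += 360.0
    return SinusoidFit(freq=freq, amplitude=float(amp), phase_deg=float(phase_deg),
                       offset=float(off), n_used=int(len(t)),
                       rmse=float(np.sqrt(np.mean(sol.fun ** 2))))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def build_exclusion_mask(v: EyeTrace, fit1: SinusoidFit,
                         threshold_dps: float = 31.0,
                         margin_s: float = 0.050,
                         min_segment_s: float = 0.010,
                         edge_samples: int = 0) -> ExclusionMask:
    """Saccade/artifact exclusion from first-pass residuals.

    Samples with ``|v - fit1| > threshold`` (strict) start an excluded run;
    each run is dilated by ``margin_s`` on both sides (overlapping windows
    merge); any retained run shorter than ``min_segment_s`` is then excluded
    too.  ``edge_samples`` at each end are flagged as edge and kept out of the
    excluded-fraction bookkeeping entirely.
    """
    n = len(v)
    fs = v.sample_rate
    margin_n = int(round(margin_s * fs))
    min_seg_n = int(round(min_segment_s * fs))
    core = slice(edge_samples, n - edge_samples if edge_samples else n)

    residual = v.values - fit1.reconstruct(v.t)
    reasons = np.zeros(n, dtype=np.int8)
    if edge_samples:
        reasons[:edge_samples] = REASON_EDGE
        reasons[n - edge_samples:] = REASON_EDGE

    over = np.zeros(n, dtype=bool)
    over[core] = np.abs(residual[core]) > threshold_dps

    excluded = np.zeros(n, dtype=bool)
    lo, hi = core.start, core.stop
    for i0, i1 in _runs(over):
        excluded[max(i0 - margin_n, lo):min(i1 + margin_n, hi)] = True
    reasons[excluded] = REASON_MARGIN
    reasons[over] = REASON_SACCADE

    # discard retained (good) runs shorter than the minimum segment
    retained_core = ~excluded
    retained_core[:lo] = False
    retained_core[hi:] = False
    for i0, i1 in _runs(retained_core):
        if i1 - i0 < min_seg_n:
            excluded[i0:i1] = True
            reasons[i0:i1] = REASON_SHORT_SEGMENT

    n_core = hi - lo
    frac = float(excluded[core].sum() / n_core) if n_core else 0.0
    full_excluded = excluded.copy()
    if edge_samples:
        full_excluded[:lo] = True
        full_excluded[hi:] = True
    return ExclusionMask(excluded=full_excluded, reasons=reasons,
                         excluded_fraction=frac, threshold_dps=threshold_dps,
                         margin_s=margin_s, min_segment_s=min_segment_s)


def analyze_trial(v: EyeTrace, freq: float,
                  threshold_dps: float = 31.0,
                  margin_s: float = 0.050,
                  min_segment_s: float = 0.010,
                  max_excluded_fraction: float = 0.45,
                  edge_samples: int = 0) -> TrialResult:
    """Two-pass analysis of one test's velocity trace.

    Pass 1 fits all (non-edge) samples; the exclusion mask is built from its
    residuals; the trial is invalid if the excluded fraction exceeds
    ``max_excluded_fraction`` (strictly); otherwise pass 2 refits on the
    retained samples and provides the response amplitude.
    """
    n = len(v)
    non_edge = np.ones(n, dtype=bool)
    if edge_samples:
        non_edge[:edge_samples] = False
        non_edge[n - edge_samples:] = False
    fit1 = fit_sinusoid(v, freq, include=non_edge)
    mask = build_exclusion_mask(v, fit1, threshold_dps, margin_s, min_segment_s,
                                edge_samples=edge_samples)
    valid = mask.excluded_fraction <= max_excluded_fraction
    if not valid:
        return TrialResult(fit_first_pass=fit1, mask=mask, valid=False)
    fit2 = fit_sinusoid(v, freq, include=mask.retained)
    return TrialResult(fit_first_pass=fit1, mask=mask, valid=True, fit=fit2)


def analyze_test(position: EyeTrace, freq: float,
                 filter_spec: FilterSpec = FilterSpec(),
                 **kwargs) -> TrialResult:
    """Full chain on a raw eye-position trace: filter, differentiate, two-pass fit."""
    v, half = preprocess(position, filter_spec)
    return analyze_trial(v, freq, edge_samples=half, **kwargs)
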