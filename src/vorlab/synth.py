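"""Synthetic eye-movement recordings with known ground truth.

Generates head-fixed VOR/OKR sessions: sinusoidal eye-velocity responses to a
±10 deg/s vestibular or optokinetic stimulus, with caller-controlled gain,
phase, offset, injected saccades (minimum-jerk position steps) and additive
measurement noise, organised into the testing-block structure of the behavioural
protocols (3 × 45 s VOR tests separated by 10 s, baseline + one testing block
after each 10 min training block; 60 × 50 s OKR blocks).

Sign conventions
----------------
Stimulus velocity is ``A·sin(2πft)``. For VOR tasks the compensatory eye
response opposes the head, so phase 0 means eye velocity ``-gain·A·sin(2πft)``;
for OKR, phase 0 means the eye follows the drum, ``+gain·A·sin(2πft)``.
Positive ``phase_deg`` leads the ideal response.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Task",
    "ProtocolSpec",
    "EyeTrace",
    "SaccadeEvent",
    "GroundTruth",
    "Session",
    "generate_stimulus",
    "synthesize_eye_position",
    "minimum_jerk_step",
    "inject_saccades",
    "draw_saccade_events",
    "add_noise",
    "generate_session",
    "synthesize_test",
    "phase_relative_to_ideal",
    "write_session",
    "read_trace_csv",
]

TRACE_COLUMNS = ["time_s", "eye_position_deg", "vestibular_velocity_dps", "visual_velocity_dps"]


class Task(str, enum.Enum):
    """Training/testing protocol identity; fixes the visual-vestibular pairing."""

    VOR_INCREASE = "vor_increase"   # visual opposite to vestibular
    VOR_DECREASE = "vor_decrease"   # visual equal to vestibular (drum head-fixed)
    VESTIBULAR_ONLY = "vestibular_only"
    OKR = "okr"                     # drum only, turntable stationary


@dataclass(frozen=True)
class ProtocolSpec:
    """Stimulus and block schedule for one behavioural session.

    ``stim_freq`` is 1.0 or 0.5 Hz in the standard protocols; ``stim_peak_velocity``
    is the ±10 deg/s peak of the sinusoidal stimulus. VOR sessions interleave
    testing blocks (``tests_per_block`` × ``test_len_s`` tests in the dark,
    ``inter_test_gap_s`` apart) with ``n_training_blocks`` training blocks of
    ``training_block_s`` each; OKR sessions measure during the training blocks
    themselves.
    """

    task: Task
    stim_freq: float = 1.0
    stim_peak_velocity: float = 10.0
    n_training_blocks: int = 3
    training_block_s: float = 600.0
    test_len_s: float = 45.0
    tests_per_block: int = 3
    inter_test_gap_s: float = 10.0
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        self_task = Task(self.task)
        object.__setattr__(self, "task", self_task)
        if self.stim_freq <= 0:
            raise ValueError("stim_freq must be positive")
        if self.stim_peak_velocity <= 0:
            raise ValueError("stim_peak_velocity must be positive")
        for name in ("n_training_blocks", "training_block_s", "test_len_s",
                     "tests_per_block", "inter_test_gap_s", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def vor(cls, task: Task | str = Task.VOR_INCREASE, stim_freq: float = 1.0, **kw) -> "ProtocolSpec":
        """Standard VOR session: 3×45 s tests per block, 3×10 min training."""
        return cls(task=Task(task), stim_freq=stim_freq, test_len_s=45.0, **kw)

    @classmethod
    def okr(cls, stim_freq: float = 1.0, **kw) -> "ProtocolSpec":
        """Standard OKR adaptation session: 60 × 50 s lit blocks, 10 s dark gaps."""
        kw.setdefault("n_training_blocks", 60)
        kw.setdefault("training_block_s", 50.0)
        return cls(task=Task.OKR, stim_freq=stim_freq, test_len_s=50.0,
                   tests_per_block=1, **kw)

    @property
    def n_testing_blocks(self) -> int:
        """Baseline plus one testing block after each training block (VOR);
        every training block is a measurement block for OKR."""
        if self.task is Task.OKR:
            return self.n_training_blocks
        return self.n_training_blocks + 1

    def block_time_min(self, block_index: int) -> float:
        """Cumulative training time (minutes) at which testing block *i* occurs."""
        if self.task is Task.OKR:
            return (block_index + 1) * self.training_block_s / 60.0
        return block_index * self.training_block_s / 60.0


@dataclass
class EyeTrace:
    """Uniformly sampled eye position (deg) or velocity (deg/s) time series."""

    t: np.ndarray
    values: np.ndarray
    kind: str  # "position" | "velocity"
    sample_rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("position", "velocity"):
            raise ValueError(f"kind must be 'position' or 'velocity', got {self.kind!r}")
        if self.t.shape != self.values.shape or self.t.ndim != 1:
            raise ValueError("t and values must be 1-D arrays of equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
                raise ValueError("trace must be uniformly sampled")
            if not math.isclose(1.0 / dt[0], self.sample_rate, rel_tol=1e-6):
                raise ValueError("sample_rate inconsistent with time grid")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate

    def copy(self) -> "EyeTrace":
        return EyeTrace(self.t.copy(), self.values.copy(), self.kind, self.sample_rate)


@dataclass(frozen=True)
class SaccadeEvent:
    """One injected saccade / movement artifact.

    ``peak_velocity_dps`` is signed; the minimum-jerk step's position amplitude
    follows from (duration, peak velocity)."""

    onset_s: float
    duration_s: float
    peak_velocity_dps: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("saccade duration must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """True response parameters for one testing block, for recovery checks."""

    gain: float
    phase_deg: float = 0.0
    offset_dps: float = 0.0
    noise_sd_dps: float = 0.0
    saccade_rate_hz: float = 0.0
    saccade_peak_range_dps: tuple[float, float] = (40.0, 200.0)
    saccade_duration_s: float = 0.05

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        if self.noise_sd_dps < 0:
            raise ValueError("noise sd must be >= 0")
        if self.saccade_rate_hz < 0:
            raise ValueError("saccade rate must be >= 0")


def _time_grid(spec: ProtocolSpec, duration_s: float | None = None) -> np.ndarray:
    n = round((duration_s if duration_s is not None else spec.test_len_s) * spec.sample_rate)
    return np.arange(n) / spec.sample_rate


def generate_stimulus(spec: ProtocolSpec, duration_s: float | None = None,
                      segment: str = "test") -> tuple[EyeTrace, EyeTrace]:
    """Vestibular and visual stimulus-velocity traces for one test or training segment.

    During VOR tests the drum is dark/stationary, so the visual trace is zero;
    during training segments the pairing follows the task: vor_decrease pairs
    identical drum and head motion, vor_increase pairs opposite motion,
    vestibular_only has no drum, okr has no head motion.
    """
    if segment not in ("test", "training"):
        raise ValueError("segment must be 'test' or 'training'")
    t = _time_grid(spec, duration_s)
    s = spec.stim_peak_velocity * np.sin(2 * np.pi * spec.stim_freq * t)
    zero = np.zeros_like(t)
    task = Task(spec.task)
    if task is Task.OKR:
        vest, vis = zero, s
    elif segment == "test" or task is Task.VESTIBULAR_ONLY:
        vest, vis = s, zero
    elif task is Task.VOR_DECREASE:
        vest, vis = s, s.copy()
    elif task is Task.VOR_INCREASE:
        vest, vis = s, -s
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown task {task}")
    fs = spec.sample_rate
    return EyeTrace(t, vest, "velocity", fs), EyeTrace(t, vis, "velocity", fs)


def _response_sign(task: Task) -> float:
    # VOR opposes the head; OKR follows the drum.
    return 1.0 if Task(task) is Task.OKR else -1.0


def synthesize_eye_position(truth: GroundTruth, stimulus: EyeTrace,
                            spec: ProtocolSpec) -> EyeTrace:
    """Noise- and saccade-free eye-position trace for a sinusoidal stimulus.

    The analytic eye velocity is
    ``offset + sign·gain·A·sin(2πft + φ)`` with the compensatory sign
    convention; the returned position is its exact integral (no numerical
    integration error).
    """
    if stimulus.kind != "velocity":
        raise ValueError("stimulus must be a velocity trace")
    f = spec.stim_freq
    A = spec.stim_peak_velocity
    phi = np.deg2rad(truth.phase_deg)
    sign = _response_sign(spec.task)
    w = 2 * np.pi * f
    t = stimulus.t
    pos = (-sign * truth.gain * A * np.cos(w * t + phi) / w
           + truth.offset_dps * t)
    pos -= pos[0]
    return EyeTrace(t, pos, "position", stimulus.sample_rate)


def minimum_jerk_step(t_rel: np.ndarray, duration_s: float, amplitude_deg: float) -> np.ndarray:
    """Minimum-jerk position step: smooth 10τ³−15τ⁴+6τ⁵ profile on [0, duration]."""
    tau = np.clip(t_rel / duration_s, 0.0, 1.0)
    return amplitude_deg * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


# peak of d/dτ(10τ³−15τ⁴+6τ⁵) at τ=1/2 is 15/8; converts peak velocity to amplitude
_MIN_JERK_PEAK = 15.0 / 8.0


def inject_saccades(trace: EyeTrace, events: list[SaccadeEvent],
                    min_separation_s: float = 0.05) -> tuple[EyeTrace, list[SaccadeEvent]]:
    """Add minimum-jerk position steps at the listed events.

    Events must fit inside the trace and respect ``min_separation_s`` between
    the end of one and the onset of the next; the event log is returned for
    ground-truth comparison.
    """
    if trace.kind != "position":
        raise ValueError("saccades are injected into a position trace")
    out = trace.copy()
    events = sorted(events, key=lambda e: e.onset_s)
    prev_end = -np.inf
    for ev in events:
        if ev.onset_s < 0 or ev.onset_s + ev.duration_s > trace.duration:
            raise ValueError(f"saccade at {ev.onset_s}s extends past trace end")
        if ev.onset_s - prev_end < min_separation_s:
            raise ValueError("saccades closer than the minimum separation")
        prev_end = ev.onset_s + ev.duration_s
        amp = ev.peak_velocity_dps * ev.duration_s / _MIN_JERK_PEAK
        i0 = int(round(ev.onset_s * trace.sample_rate))
        out.values[i0:] += minimum_jerk_step(trace.t[i0:] - trace.t[i0],
                                             ev.duration_s, amp)
    return out, events


def draw_saccades(rng: np.random.Generator, duration_s: float, rate_hz: float,
                  peak_range_dps: tuple[float, float] = (40.0, 200.0),
                  saccade_duration_s: float = 0.05,
                  min_separation_s: float = 0.05) -> list[SaccadeEvent]:
    """Poisson saccade times (thinned to respect the minimum separation),
    uniform signed peak velocities in ``peak_range_dps``."""
    n = rng.poisson(rate_hz * duration_s)
    onsets = np.sort(rng.uniform(0, duration_s - saccade_duration_s, size=n))
    events: list[SaccadeEvent] = []
    prev_end = -np.inf
    lo, hi = peak_range_dps
    for onset in onsets:
        if onset - prev_end < min_separation_s:
            continue
        peak = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        events.append(SaccadeEvent(float(onset), saccade_duration_s, float(peak)))
        prev_end = onset + saccade_duration_s
    return events


# kept under the name used in the docs/CLI
draw_saccade_events = draw_saccades


def add_noise(trace: EyeTrace, noise_sd: float,
              rng: np.random.Generator | int | None = None) -> EyeTrace:
    """Add white Gaussian noise (same units as the trace); seeded, reproducible."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    out = trace.copy()
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        out.values = out.values + gen.normal(0.0, noise_sd, size=len(out))
    return out


@dataclass
class TestRecording:
    """One synthesized test: traces plus its ground truth."""

    block_index: int
    test_index: int
    block_time_min: float
    eye_position: EyeTrace
    vestibular: EyeTrace
    visual: EyeTrace
    truth: GroundTruth
    saccade_events: list[SaccadeEvent] = field(default_factory=list)


@dataclass
class Session:
    spec: ProtocolSpec
    seed: int
    tests: list[TestRecording]

    def block(self, i: int) -> list[TestRecording]:
        return [r for r in self.tests if r.block_index == i]

    def manifest(self) -> dict:
        m = {
            "protocol": {k: (v.value if isinstance(v, Task) else v)
                         for k, v in dataclasses.asdict(self.spec).items()},
            "seed": self.seed,
            "phase_convention": ("phase 0 = ideal compensatory response "
                                 "(VOR: eye opposes head; OKR: eye follows drum)"),
            "blocks": [],
        }
        for b in range(self.spec.n_testing_blocks):
            recs = self.block(b)
            m["blocks"].append({
                "block_index": b,
                "block_time_min": recs[0].block_time_min,
                "ground_truth": dataclasses.asdict(recs[0].truth),
                "tests": [{
                    "test_index": r.test_index,
                    "file": f"block{b:02d}_test{r.test_index}.csv",
                    "n_saccades": len(r.saccade_events),
                    "saccades": [dataclasses.asdict(e) for e in r.saccade_events],
                } for r in recs],
            })
        return m


def _synthesize_test(spec: ProtocolSpec, truth: GroundTruth,
                     rng: np.random.Generator) -> tuple[EyeTrace, EyeTrace, EyeTrace, list[SaccadeEvent]]:
    vest, vis = generate_stimulus(spec)
    pos = synthesize_eye_position(truth, vest if Task(spec.task) is not Task.OKR else vis, spec)
    events = draw_saccades(rng, spec.test_len_s, truth.saccade_rate_hz,
                           truth.saccade_peak_range_dps, truth.saccade_duration_s)
    pos, events = inject_saccades(pos, events)
    if truth.noise_sd_dps > 0:
        # sensor noise modelled as white noise in eye *velocity*; integrate so
        # that differentiation in the analysis chain sees noise of this SD
        vnoise = rng.normal(0.0, truth.noise_sd_dps, size=len(pos))
        pos.values = pos.values + np.cumsum(vnoise) / spec.sample_rate
    return pos, vest, vis, events


def synthesize_test(spec: ProtocolSpec, truth: GroundTruth,
                    rng: np.random.Generator | int | None = None) -> TestRecording:
    """One stand-alone test period (traces + ground truth), outside any session."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pos, vest, vis, events = _synthesize_test(spec, truth, gen)
    return TestRecording(block_index=0, test_index=0, block_time_min=0.0,
                         eye_position=pos, vestibular=vest, visual=vis,
                         truth=truth, saccade_events=events)


def phase_relative_to_ideal(fitted_phase_deg: float, task: Task | str) -> float:
    """Convert a fitted phase (re ``sin(2πft)`` stimulus) to the convention
    where 0 = ideal compensatory response (VOR opposes head, OKR follows drum)."""
    shift = 0.0 if _response_sign(Task(task)) > 0 else 180.0
    phase = (fitted_phase_deg - shift + 180.0) % 360.0 - 180.0
    return phase + 360.0 if phase <= -180.0 else phase


def generate_session(spec: ProtocolSpec, truth_schedule: list[GroundTruth],
                     seed: int = 0) -> Session:
    """Synthesize every test period of a session.

    ``truth_schedule`` holds one :class:`GroundTruth` per testing block
    (VOR: baseline + one per training block; OKR: one per 50 s block). Only the
    measured (in-the-dark / lit-drum) test periods are synthesized.
    """
    if len(truth_schedule) == 0:
        raise ValueError("truth_schedule must not be empty")
    if len(truth_schedule) != spec.n_testing_blocks:
        raise ValueError(
            f"truth_schedule has {len(truth_schedule)} entries; "
            f"protocol defines {spec.n_testing_blocks} testing blocks")
    root = np.random.default_rng(seed)
    tests: list[TestRecording] = []
    for b, truth in enumerate(truth_schedule):
        for k in range(spec.tests_per_block):
            pos, vest, vis, events = _synthesize_test(spec, truth, root)
            tests.append(TestRecording(
                block_index=b, test_index=k,
                block_time_min=spec.block_time_min(b),
                eye_position=pos, vestibular=vest, visual=vis,
                truth=truth, saccade_events=events))
    return Session(spec=spec, seed=seed, tests=tests)


def write_session(session: Session, outdir: str | pathlib.Path) -> pathlib.Path:
    """Write one CSV per test plus a YAML manifest; returns the manifest path."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for r in session.tests:
        df = pd.DataFrame({
            "time_s": r.eye_position.t,
            "eye_position_deg": r.eye_position.values,
            "vestibular_velocity_dps": r.vestibular.values,
            "visual_velocity_dps": r.visual.values,
        })
        df.to_csv(outdir / f"block{r.block_index:02d}_test{r.test_index}.csv",
                  index=False)
    path = outdir / "manifest.yaml"
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(session.manifest(), fh, sort_keys=False)
    return path


def read_trace_csv(path: str | pathlib.Path) -> dict[str, EyeTrace]:
    """Read a test CSV back into eye/vestibular/visual traces."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file missing columns: {missing}")
    t = df["time_s"].to_numpy()
    fs = 1.0 / (t[1] - t[0])
    return {
        "eye_position": EyeTrace(t, df["eye_position_deg"].to_numpy(), "position", fs),
        "vestibular": EyeTrace(t, df["vestibular_velocity_dps"].to_numpy(), "velocity", fs),
        "visual": EyeTrace(t, df["visual_velocity_dps"].to_numpy(), "velocity", fs),
    }
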