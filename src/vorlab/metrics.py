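"""Block measures, gains, and learning curves (ΔVOR / ΔOKR).

Per-trial fitted amplitudes are averaged within each testing block (valid
trials only), converted to gain by dividing by the stimulus peak velocity, and
expressed as percent change relative to a pre-training baseline:

* ΔVOR: percent change of the block amplitude after each 10 min training block
  relative to the baseline block measured before training.
* ΔOKR: baseline = mean of blocks 1-3, post = mean of blocks 58-60, with
  intermediate checkpoints at blocks 10/20/30/40/50 relative to that baseline.

Percent changes are computed on amplitudes; gains are carried alongside and,
because amplitude and gain share the stimulus peak, the two give identical
percent changes.  Blocks with no valid trial propagate as missing data, never
as zeros.
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .desaccade import TrialResult

__all__ = [
    "BlockMeasure",
    "LearningCurve",
    "block_measure",
    "vor_learning_curve",
    "okr_learning_curve",
    "pretraining_curve",
    "session_table",
]

OKR_CHECKPOINT_BLOCKS = (10, 20, 30, 40, 50)


@dataclass(frozen=True)
class BlockMeasure:
    """One testing block: mean amplitude over its valid trials."""

    block_time_min: float
    amplitude: float          # deg/s, mean over valid trials
    gain: float               # amplitude / stimulus peak velocity
    n_valid: int

    def __post_init__(self) -> None:
        if self.n_valid < 1:
            raise ValueError("BlockMeasure requires at least one valid trial")


@dataclass
class LearningCurve:
    """Percent change of the response amplitude relative to a baseline."""

    task: str
    baseline_amplitude: float
    block_time_min: list[float]
    amplitude: list[float]
    gain: list[float]
    delta_pct: list[float]
    checkpoints: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "block_time_min": self.block_time_min,
            "amplitude_dps": self.amplitude,
            "gain": self.gain,
            "delta_pct": self.delta_pct,
        })


def block_measure(trials: list[TrialResult], stim_peak: float,
                  block_time_min: float = 0.0) -> BlockMeasure | None:
    """Average the valid trials of one testing block.

    Returns ``None`` when no trial is valid: the block is a missing datum and
    must not be confused with a zero-amplitude response.
    """
    amps = [t.amplitude for t in trials if t.valid and t.amplitude is not None]
    if not amps:
        return None
    amp = float(np.mean(amps))
    return BlockMeasure(block_time_min=block_time_min, amplitude=amp,
                        gain=amp / stim_peak, n_valid=len(amps))


def _percent_change(amplitude: float, baseline: float) -> float:
    if baseline <= 0:
        raise ValueError("percent change undefined for non-positive baseline amplitude")
    return 100.0 * (amplitude - baseline) / baseline


def vor_learning_curve(blocks: list[BlockMeasure | None],
                       task: str = "vor") -> LearningCurve:
    """ΔVOR: percent change of each block's amplitude from the baseline block.

    ``blocks[0]`` is the pre-training baseline (required); later missing blocks
    yield NaN entries.
    """
    if not blocks or blocks[0] is None:
        raise ValueError("baseline block is required")
    base = blocks[0].amplitude
    times, amps, gains, deltas = [], [], [], []
    for i, b in enumerate(blocks):
        if b is None:
            times.append(math.nan); amps.append(math.nan)
            gains.append(math.nan); deltas.append(math.nan)
            continue
        times.append(b.block_time_min)
        amps.append(b.amplitude)
        gains.append(b.gain)
        deltas.append(_percent_change(b.amplitude, base))
    return LearningCurve(task=task, baseline_amplitude=base,
                         block_time_min=times, amplitude=amps, gain=gains,
                         delta_pct=deltas)


def okr_learning_curve(blocks: list[BlockMeasure | None],
                       checkpoint_blocks: tuple[int, ...] = OKR_CHECKPOINT_BLOCKS,
                       checkpoint_window: int = 1) -> LearningCurve:
    """ΔOKR from 60 one-minute training blocks.

    Baseline = mean amplitude of blocks 1-3; post = mean of blocks 58-60;
    ΔOKR = 100·(post - baseline)/baseline.  Checkpoints (blocks 10..50 by
    default) are reported relative to the same baseline; ``checkpoint_window``
    > 1 averages that many blocks ending at the checkpoint.
    """
    if len(blocks) < 60:
        raise ValueError("OKR session requires 60 blocks")

    def window_mean(last_block_1based: int, width: int) -> float:
        sel = blocks[last_block_1based - width:last_block_1based]
        vals = [b.amplitude for b in sel if b is not None]
        if len(vals) < width:
            raise ValueError(f"missing block in window ending at block {last_block_1based}")
        return float(np.mean(vals))

    base = window_mean(3, 3)
    post = window_mean(60, 3)
    delta_okr = _percent_change(post, base)
    checkpoints = {c: _percent_change(window_mean(c, checkpoint_window), base)
                   for c in checkpoint_blocks}

    times, amps, gains, deltas = [], [], [], []
    for b in blocks:
        if b is None:
            times.append(math.nan); amps.append(math.nan)
            gains.append(math.nan); deltas.append(math.nan)
        else:
            times.append(b.block_time_min)
            amps.append(b.amplitude)
            gains.append(b.gain)
            deltas.append(_percent_change(b.amplitude, base))
    curve = LearningCurve(task="okr", baseline_amplitude=base,
                          block_time_min=times, amplitude=amps, gain=gains,
                          delta_pct=deltas, checkpoints=checkpoints)
    curve.post_amplitude = post          # type: ignore[attr-defined]
    curve.delta_okr_pct = delta_okr      # type: ignore[attr-defined]
    return curve


def pretraining_curve(pre_blocks: list[BlockMeasure | None],
                      training_blocks: list[BlockMeasure | None],
                      task: str = "vor_pretrained") -> dict[str, LearningCurve]:
    """Pre-training followed by training, each with its own reference.

    The pre-training segment is referenced to its first (e.g. -30 min) block;
    the training segment is referenced to the measurement at training time 0,
    i.e. the last pre-training block (or the first training block when no
    pre-training was given).
    """
    if not training_blocks:
        raise ValueError("training segment is required")
    if not pre_blocks:
        return {"training": vor_learning_curve(training_blocks, task=task)}
    pre = vor_learning_curve(pre_blocks, task=task + "_pre")
    train = vor_learning_curve(training_blocks, task=task)
    return {"pre": pre, "training": train}


def session_table(curve: LearningCurve, animal_id: str = "synthetic",
                  genotype: str = "NA", task: str | None = None,
                  pretreatment: str = "none") -> pd.DataFrame:
    """Tidy per-session table: one row per testing block."""
    df = curve.to_frame()
    df.insert(0, "animal_id", animal_id)
    df.insert(1, "genotype", genotype)
    df.insert(2, "task", task or curve.task)
    df.insert(3, "pretreatment", pretreatment)
    return df


def write_summary(curve: LearningCurve, path: str | pathlib.Path) -> None:
    """Session-level JSON summary."""
    payload = {
        "task": curve.task,
        "baseline_amplitude_dps": curve.baseline_amplitude,
        "block_time_min": curve.block_time_min,
        "amplitude_dps": curve.amplitude,
        "gain": curve.gain,
        "delta_pct": curve.delta_pct,
        "checkpoints_pct": curve.checkpoints,
        "missing_blocks": [i for i, a in enumerate(curve.amplitude)
                           if isinstance(a, float) and math.isnan(a)],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
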