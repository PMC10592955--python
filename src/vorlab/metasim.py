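"""Minimal sliding-threshold (BCM-like) metaplasticity simulator.

A pool of parallel-fiber→Purkinje-cell synapses carries a weight ``w`` and a
per-synapse induction threshold ``theta`` for associative LTD.  Coactivation
events arrive stochastically; an event induces LTD (a bounded weight
decrement) only when its drive exceeds the synapse's current threshold, and
every induced LTD event slides the threshold up by ``dtheta`` — recent
plasticity, not firing rate per se, moves the threshold.  VOR-decrease-style
(LTP-inducing) training restores weights toward baseline and relaxes the
threshold back down; suppressing circuit activity (a diazepam analogue) stops
events while the threshold relaxes.

The genotype with constitutively enhanced LTD is modelled as a lowered
baseline threshold: spontaneous activity that is subthreshold in the wild type
aberrantly induces LTD, depressing weights and ratcheting the threshold above
the level that task training can reach — so training then fails to recruit the
LTD it needs, until pre-training or activity suppression resets the threshold.

All functional forms (Poisson events, linear threshold steps, exponential
relaxation, hard weight bounds) are minimal modelling choices; predictions are
qualitative/ordinal only, never fitted to behavioural data.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Genotype",
    "EpisodeKind",
    "EpisodeSpec",
    "MetaSimConfig",
    "SynapsePool",
    "make_pool",
    "step",
    "learning_readout",
    "condition_protocol",
    "run_condition",
    "run_experiment_matrix",
    "run_transience",
]


class Genotype(str, enum.Enum):
    WT = "WT"
    ENHANCED_LTD = "enhanced_LTD"


class EpisodeKind(str, enum.Enum):
    SPONTANEOUS = "spontaneous"
    LTD_TRAINING = "ltd_training"            # VOR-increase analogue
    LTP_TRAINING = "ltp_training"            # VOR-decrease / habituation analogue
    ACTIVITY_SUPPRESSION = "activity_suppression"  # diazepam analogue


@dataclass(frozen=True)
class EpisodeSpec:
    kind: EpisodeKind
    duration_min: float
    drive_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_min < 0:
            raise ValueError("episode duration must be >= 0")
        object.__setattr__(self, "kind", EpisodeKind(self.kind))


@dataclass(frozen=True)
class MetaSimConfig:
    """All model constants in one place (YAML-serializable).

    Rates are per synapse per minute; drives and thresholds share one
    arbitrary activity unit.  ``genotype_factor`` (>1) divides the wild-type
    baseline threshold to produce the enhanced-LTD genotype.
    """

    n_synapses: int = 200
    task_relevant_fraction: float = 0.5
    w_init: float = 1.0
    w_min: float = 0.0
    w_max: float = 1.0
    dw: float = 0.2                      # LTD decrement per induced event
    theta_baseline: float = 1.0          # WT threshold (activity units)
    genotype_factor: float = 2.0         # enhanced-LTD baseline = 1.0 / 2.0
    drive_spontaneous: float = 0.7       # between the two baselines
    drive_training: float = 1.5          # above both naive baselines
    rate_spontaneous: float = 0.2        # events / synapse / min
    rate_training: float = 1.0
    dtheta: float = 2.0                  # threshold step per induced LTD event
    relax_rate: float = 0.15             # /min, exponential return to baseline
    history_spontaneous_min: float = 60.0
    pretraining_min: float = 30.0
    suppression_min: float = 120.0
    training_min: float = 30.0

    def theta_for(self, genotype: Genotype) -> float:
        if Genotype(genotype) is Genotype.ENHANCED_LTD:
            return self.theta_baseline / self.genotype_factor
        return self.theta_baseline

    @classmethod
    def from_yaml(cls, path: str) -> "MetaSimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


@dataclass
class SynapsePool:
    genotype: Genotype
    w: np.ndarray
    theta: np.ndarray
    task_relevant: np.ndarray
    theta_baseline: float
    config: MetaSimConfig
    ltd_events_last_episode: int = 0

    def copy(self) -> "SynapsePool":
        return SynapsePool(self.genotype, self.w.copy(), self.theta.copy(),
                           self.task_relevant.copy(), self.theta_baseline,
                           self.config, self.ltd_events_last_episode)


def make_pool(genotype: Genotype | str, config: MetaSimConfig | None = None,
              rng: np.random.Generator | int | None = None) -> SynapsePool:
    """Naive pool: weights at ceiling, thresholds at the genotype baseline."""
    cfg = config or MetaSimConfig()
    genotype = Genotype(genotype)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = cfg.n_synapses
    n_task = int(round(cfg.task_relevant_fraction * n))
    task = np.zeros(n, dtype=bool)
    task[gen.permutation(n)[:n_task]] = True
    theta0 = cfg.theta_for(genotype)
    return SynapsePool(genotype=genotype,
                       w=np.full(n, cfg.w_init, dtype=float),
                       theta=np.full(n, theta0, dtype=float),
                       task_relevant=task, theta_baseline=theta0, config=cfg)


def _apply_events(pool: SynapsePool, eligible: np.ndarray, rate: float,
                  drive: float, duration_min: float,
                  rng: np.random.Generator) -> int:
    """Poisson coactivation events on the eligible synapses.

    Within an episode a synapse's successive events see a threshold that has
    already been raised by its earlier inductions, so the number of inductions
    out of ``k`` events is ``min(k, m)`` with ``m`` the number of dtheta steps
    that fit strictly below the drive.
    """
    cfg = pool.config
    k = np.zeros(pool.w.shape, dtype=np.int64)
    k[eligible] = rng.poisson(rate * duration_min, size=int(eligible.sum()))
    # number of inductions possible before theta reaches the drive
    headroom = (drive - pool.theta) / cfg.dtheta
    m = np.where(pool.theta < drive, np.ceil(headroom).astype(np.int64), 0)
    inductions = np.minimum(k, m)
    pool.theta += inductions * cfg.dtheta
    pool.w = np.maximum(pool.w - inductions * cfg.dw, cfg.w_min)
    return int(inductions.sum())


def step(pool: SynapsePool, episode: EpisodeSpec,
         rng: np.random.Generator | int | None = None) -> SynapsePool:
    """Advance a pool through one episode; returns a new pool.

    Spontaneous episodes drive random coactivation across all synapses;
    LTD-training targets the task-relevant synapses at the (stronger) training
    drive; LTP-training restores weights toward baseline and relaxes the
    threshold; activity suppression silences events while the threshold
    relaxes.  Thresholds never fall below the genotype baseline.
    """
    out = pool.copy()
    out.ltd_events_last_episode = 0
    if episode.duration_min == 0:
        return out
    cfg = out.config
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    kind = EpisodeKind(episode.kind)

    if kind is EpisodeKind.SPONTANEOUS:
        if episode.drive_multiplier > 0:
            out.ltd_events_last_episode = _apply_events(
                out, np.ones_like(out.task_relevant), cfg.rate_spontaneous,
                cfg.drive_spontaneous * episode.drive_multiplier,
                episode.duration_min, gen)
    elif kind is EpisodeKind.LTD_TRAINING:
        if episode.drive_multiplier > 0:
            out.ltd_events_last_episode = _apply_events(
                out, out.task_relevant, cfg.rate_training,
                cfg.drive_training * episode.drive_multiplier,
                episode.duration_min, gen)
    elif kind is EpisodeKind.LTP_TRAINING:
        decay = math.exp(-cfg.relax_rate * episode.duration_min)
        out.w = cfg.w_init - (cfg.w_init - out.w) * decay
        out.w = np.clip(out.w, cfg.w_min, cfg.w_max)
        out.theta = out.theta_baseline + (out.theta - out.theta_baseline) * decay
    elif kind is EpisodeKind.ACTIVITY_SUPPRESSION:
        decay = math.exp(-cfg.relax_rate * episode.duration_min)
        out.theta = out.theta_baseline + (out.theta - out.theta_baseline) * decay
    out.theta = np.maximum(out.theta, out.theta_baseline)
    return out


def learning_readout(before: SynapsePool, after: SynapsePool) -> float:
    """Predicted adaptive gain increase, arbitrary units.

    Mean training-period weight decrement over the task-relevant synapses,
    normalized by the single-event decrement ``dw`` (so a naive wild-type pool
    reads out ≈ 1).  Monotone in the LTD recruited where learning needs it.
    """
    task = before.task_relevant
    dec = before.w[task] - after.w[task]
    return float(np.sum(dec) / (task.sum() * before.config.dw))


PRETREATMENTS = ("none", "ltp_pretraining", "suppression_pretreatment")


def condition_protocol(pretreatment: str, cfg: MetaSimConfig) -> list[EpisodeSpec]:
    """Episode sequence preceding training for one experimental condition."""
    history = [EpisodeSpec(EpisodeKind.SPONTANEOUS, cfg.history_spontaneous_min)]
    if pretreatment == "none":
        return history
    if pretreatment == "ltp_pretraining":
        return history + [EpisodeSpec(EpisodeKind.LTP_TRAINING, cfg.pretraining_min)]
    if pretreatment == "suppression_pretreatment":
        return history + [EpisodeSpec(EpisodeKind.ACTIVITY_SUPPRESSION,
                                      cfg.suppression_min, drive_multiplier=0.0)]
    raise ValueError(f"unknown pretreatment {pretreatment!r}")


def run_condition(genotype: Genotype | str, pretreatment: str,
                  cfg: MetaSimConfig, rng: np.random.Generator,
                  extra_pre_training: list[EpisodeSpec] | None = None) -> float:
    """One replicate: history + pretreatment (+ optional extras) + training."""
    pool = make_pool(genotype, cfg, rng)
    for ep in condition_protocol(pretreatment, cfg):
        pool = step(pool, ep, rng)
    for ep in (extra_pre_training or []):
        pool = step(pool, ep, rng)
    before = pool
    after = step(pool, EpisodeSpec(EpisodeKind.LTD_TRAINING, cfg.training_min), rng)
    return learning_readout(before, after)


def run_experiment_matrix(cfg: MetaSimConfig | None = None, n_seeds: int = 50,
                          seed: int = 0) -> pd.DataFrame:
    """Predicted learning for genotype × pre-treatment, ``n_seeds`` replicates.

    Returns a tidy frame (genotype, pretreatment, replicate, readout); use
    ``.groupby(["genotype", "pretreatment"]).readout.agg(["mean", "std"])``
    for the condition summary.
    """
    cfg = cfg or MetaSimConfig()
    root = np.random.default_rng(seed)
    rows = []
    for genotype in (Genotype.WT, Genotype.ENHANCED_LTD):
        for pre in PRETREATMENTS:
            for rep in range(n_seeds):
                rng = np.random.default_rng(root.integers(2**31))
                rows.append({"genotype": genotype.value, "pretreatment": pre,
                             "replicate": rep,
                             "readout": run_condition(genotype, pre, cfg, rng)})
    return pd.DataFrame(rows)


def run_transience(cfg: MetaSimConfig | None = None, n_seeds: int = 50,
                   seed: int = 0) -> pd.DataFrame:
    """Deficit returns after suppression ends.

    The enhanced-LTD pool is trained either right after activity suppression
    or after suppression followed by a resumed spontaneous period equal to the
    original history; the latter should re-express the learning deficit.
    """
    cfg = cfg or MetaSimConfig()
    root = np.random.default_rng(seed)
    rows = []
    resumed = [EpisodeSpec(EpisodeKind.SPONTANEOUS, cfg.history_spontaneous_min)]
    for rep in range(n_seeds):
        rng = np.random.default_rng(root.integers(2**31))
        immediate = run_condition(Genotype.ENHANCED_LTD, "suppression_pretreatment",
                                  cfg, rng)
        rng = np.random.default_rng(root.integers(2**31))
        delayed = run_condition(Genotype.ENHANCED_LTD, "suppression_pretreatment",
                                cfg, rng, extra_pre_training=resumed)
        rows.append({"replicate": rep, "after_suppression": immediate,
                     "after_resumed_activity": delayed})
    return pd.DataFrame(rows)
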