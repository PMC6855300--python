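"""Seeded synthetic game sessions, ground truth, and classifier scores.

The generator emulates the statistical structure the extraction framework
assumes: prompt regions tiling a 90-second session sampled at 5 frames per
second; a per-class interpretation lag at each region start during which
the child still shows the previous expression (or neutral); a trailing
decay before each prompt change during which the face relaxes to neutral;
imperfect expression in the region interior; unlabelable frames; and
per-provider confidence vectors whose expected score for the true label
strictly dominates every other label (for any concentration > 0), with
provider-specific sharpness, miss rates, and on-disk score dialects.

One global seed drives independent per-stream generators (session
structure vs. each provider's scores) via ``numpy.random.SeedSequence``
spawn keys, so adding a provider never perturbs session structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .labels import CANONICAL_EMOTIONS, EmotionLabel
from .models import (
    ConfidenceVector,
    Frame,
    PromptRegion,
    RaterAnnotation,
    SessionMeta,
)
from . import io as fsio

#: Per-class interpretation lags and trailing decays (seconds); the defaults
#: are the per-class optima observed in the source study's sessions.
DEFAULT_ONSET_LAG: dict[EmotionLabel, float] = {
    EmotionLabel.NEUTRAL: 2.2,
    EmotionLabel.HAPPY: 0.0,
    EmotionLabel.SAD: 0.4,
    EmotionLabel.SURPRISED: 0.4,
    EmotionLabel.SCARED: 1.0,
    EmotionLabel.DISGUSTED: 0.6,
    EmotionLabel.ANGRY: 0.4,
}
DEFAULT_DECAY: dict[EmotionLabel, float] = {
    EmotionLabel.NEUTRAL: 0.0,
    EmotionLabel.HAPPY: 0.0,
    EmotionLabel.SAD: 0.4,
    EmotionLabel.SURPRISED: 1.6,
    EmotionLabel.SCARED: 1.0,
    EmotionLabel.DISGUSTED: 1.8,
    EmotionLabel.ANGRY: 0.6,
}

PerClass = Union[float, Mapping[EmotionLabel, float]]


def _per_class(value: PerClass, default: float = 0.0) -> dict[EmotionLabel, float]:
    if isinstance(value, (int, float)):
        return {e: float(value) for e in CANONICAL_EMOTIONS}
    out = {e: default for e in CANONICAL_EMOTIONS}
    out.update(value)
    return out


@dataclass(frozen=True)
class ProviderProfile:
    """A synthetic classifier: score sharpness, availability, and dialect.

    ``concentration`` controls how strongly scores pile on the true label:
    vectors are Dirichlet draws with alpha = 1 everywhere except
     1 + concentration on the true label, so the true label's expected
    score, (1 + c) / (7 + c), strictly exceeds every other label's,
    1 / (7 + c), for any c > 0 (the calibration threshold is therefore 0).
    ``concentration = inf`` yields exact one-hot vectors.
    """

    provider_id: str
    concentration: float = 4.0
    miss_rate: float = 0.05
    scale_dialect: str = "unit"


def default_providers() -> tuple[ProviderProfile, ...]:
    """Three miscalibrated providers: sharp, moderate, and diffuse scores,
    with differing availability and on-disk scales."""
    return (
        ProviderProfile("sim_sharp", concentration=6.0, miss_rate=0.05, scale_dialect="unit"),
        ProviderProfile("sim_mid", concentration=3.0, miss_rate=0.10, scale_dialect="percent"),
        ProviderProfile("sim_soft", concentration=1.5, miss_rate=0.15, scale_dialect="unit"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for synthetic sessions and scores.

    Defaults encode the study conditions: 90 s sessions at 5 fps; region
    durations uniform in 3-10 s (about 12 prompts per session, and long
    enough that lag + decay never covers a whole region); p_express = 0.8
    in the interior (boundary densities land in the observed 35-70% band);
    p_invalid = 0.12 (165 of 1350 frames were unlabelable); off-target
    expression reverts mostly to neutral.
    """

    duration: float = 90.0
    fps: float = 5.0
    region_duration_range: tuple[float, float] = (3.0, 10.0)
    emotion_weights: Mapping[EmotionLabel, float] = field(
        default_factory=lambda: {e: 1.0 for e in CANONICAL_EMOTIONS}
    )
    onset_lag: PerClass = field(default_factory=lambda: dict(DEFAULT_ONSET_LAG))
    decay: PerClass = field(default_factory=lambda: dict(DEFAULT_DECAY))
    p_express: float = 0.8
    confusion_weights: Mapping[EmotionLabel, float] = field(
        default_factory=lambda: {
            e: (3.0 if e is EmotionLabel.NEUTRAL else 1.0) for e in CANONICAL_EMOTIONS
        }
    )
    p_invalid: float = 0.12
    provider_profiles: tuple[ProviderProfile, ...] = field(
        default_factory=default_providers
    )
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.region_duration_range
        if not 0 < lo <= hi:
            raise ValueError("region_duration_range must satisfy 0 < min <= max")
        for p in (self.p_express, self.p_invalid):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        weights = list(self.emotion_weights.values())
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("emotion weights must be non-negative, not all zero")
        lag = _per_class(self.onset_lag)
        dec = _per_class(self.decay)
        for e, w in self.emotion_weights.items():
            if w > 0 and lag[e] + dec[e] >= lo:
                raise ValueError(
                    f"onset lag + decay for {e.value} ({lag[e]} + {dec[e]}) must be "
                    f"shorter than the minimum region duration {lo}"
                )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _weighted_choice(
    rng: np.random.Generator, weights: Mapping[EmotionLabel, float]
) -> EmotionLabel:
    emotions = [e for e in CANONICAL_EMOTIONS if weights.get(e, 0.0) > 0]
    w = np.array([weights[e] for e in emotions], dtype=float)
    return emotions[int(rng.choice(len(emotions), p=w / w.sum()))]


def simulate_session(
    cfg: SimulationConfig,
    seed: Optional[int] = None,
    session_index: int = 0,
    session_id: Optional[str] = None,
) -> tuple[SessionMeta, tuple[Frame, ...]]:
    """One synthetic session: meta plus frames carrying true labels.

    Frame *i* sits at ``i / fps``. Its label is, in order of precedence:
    absent with probability p_invalid (no usable face); during the onset
    lag, the previous region's emotion with probability 0.5 else neutral
    (neutral for the first region); during the trailing decay, neutral;
    otherwise the region's emotion with probability p_express, else a
    confusion-weighted off-target label.
    """
    seed = cfg.seed if seed is None else seed
    sid = session_id or f"s{session_index:03d}"
    rng = _rng(seed, 0, session_index)
    lo, hi = cfg.region_duration_range
    lag = _per_class(cfg.onset_lag)
    dec = _per_class(cfg.decay)

    regions: list[PromptRegion] = []
    t = 0.0
    while t < cfg.duration - 1e-9:
        d = float(rng.uniform(lo, hi))
        t_end = min(t + d, cfg.duration)
        regions.append(
            PromptRegion(
                region_index=len(regions),
                emotion=_weighted_choice(rng, cfg.emotion_weights),
                t_start=t,
                t_end=t_end,
                point_awarded=bool(rng.random() < 0.7),
            )
        )
        t = t_end
    meta = SessionMeta(
        session_id=sid, regions=tuple(regions), duration=cfg.duration, fps=cfg.fps
    )

    off_target = dict(cfg.confusion_weights)
    frames: list[Frame] = []
    for i in range(meta.n_frames()):
        ts = i / cfg.fps
        region = meta.region_at(ts)
        label: Optional[EmotionLabel]
        if rng.random() < cfg.p_invalid:
            label = None
        elif region is None:  # cannot happen with tiling regions; kept defensive
            label = EmotionLabel.NEUTRAL
        else:
            target = region.emotion
            if ts < region.t_start + lag[target] - 1e-9:
                prev = (
                    regions[region.region_index - 1].emotion
                    if region.region_index > 0
                    else EmotionLabel.NEUTRAL
                )
                label = prev if rng.random() < 0.5 else EmotionLabel.NEUTRAL
            elif ts >= region.t_end - dec[target] - 1e-9:
                label = EmotionLabel.NEUTRAL
            elif rng.random() < cfg.p_express:
                label = target
            else:
                weights = {e: w for e, w in off_target.items() if e is not target}
                if not any(w > 0 for w in weights.values()):
                    weights = {EmotionLabel.NEUTRAL: 1.0}
                label = _weighted_choice(rng, weights)
        frames.append(Frame(frame_id=f"{sid}-f{i:04d}", timestamp=ts, true_label=label))
    return meta, tuple(frames)


def simulate_scores(
    frames: Sequence[Frame],
    cfg: SimulationConfig,
    seed: Optional[int] = None,
    session_index: int = 0,
) -> list[ConfidenceVector]:
    """Per-provider confidence vectors for labeled and unlabeled frames.

    Labeled frames get concentration-biased Dirichlet vectors (see
    :class:`ProviderProfile`); unlabeled frames get exchangeable vectors.
    Each provider independently misses a frame with its miss rate.
    """
    if not cfg.provider_profiles:
        raise ValueError("at least one provider profile is required")
    seed = cfg.seed if seed is None else seed
    n = len(CANONICAL_EMOTIONS)
    index = {e: i for i, e in enumerate(CANONICAL_EMOTIONS)}
    vectors: list[ConfidenceVector] = []
    for p_idx, profile in enumerate(cfg.provider_profiles):
        rng = _rng(seed, 1, session_index, p_idx)
        for frame in frames:
            if rng.random() < profile.miss_rate:
                continue
            if frame.true_label is not None and math.isinf(profile.concentration):
                values = np.zeros(n)
                values[index[frame.true_label]] = 1.0
            else:
                alpha = np.ones(n)
                if frame.true_label is not None:
                    alpha[index[frame.true_label]] += profile.concentration
                values = rng.dirichlet(alpha)
            vectors.append(
                ConfidenceVector(
                    frame_id=frame.frame_id,
                    provider_id=profile.provider_id,
                    scores={e: float(values[index[e]]) for e in CANONICAL_EMOTIONS},
                )
            )
    return vectors


def perfect_rater_annotations(
    frames: Sequence[Frame], raters: tuple[str, str] = ("r1", "r2")
) -> list[RaterAnnotation]:
    """Two synthetic raters who reproduce the true labels exactly."""
    return [
        RaterAnnotation(frame_id=f.frame_id, rater_id=r, label=f.true_label)
        for f in frames
        for r in raters
    ]


@dataclass(frozen=True)
class SessionBundle:
    meta: SessionMeta
    frames: tuple[Frame, ...]
    vectors: tuple[ConfidenceVector, ...]


def simulate_bundle(
    cfg: SimulationConfig, n_sessions: int, seed: Optional[int] = None
) -> list[SessionBundle]:
    """*n_sessions* independent sessions plus scores from one global seed."""
    seed = cfg.seed if seed is None else seed
    bundles = []
    for i in range(n_sessions):
        meta, frames = simulate_session(cfg, seed=seed, session_index=i)
        vectors = simulate_scores(frames, cfg, seed=seed, session_index=i)
        bundles.append(SessionBundle(meta=meta, frames=frames, vectors=tuple(vectors)))
    return bundles


def write_bundle(bundles: Sequence[SessionBundle], cfg: SimulationConfig, out_dir: Union[str, Path]) -> list[Path]:
    """Write each session in the external formats: meta JSON, a perfect-rater
    annotation CSV, and per-provider JSON-lines in each provider's dialect."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dialect_of = {p.provider_id: p.scale_dialect for p in cfg.provider_profiles}
    manifest = out / "providers.json"
    manifest.write_text(
        json.dumps({"providers": dialect_of}, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    written: list[Path] = [manifest]
    for bundle in bundles:
        sid = bundle.meta.session_id
        meta_path = out / f"{sid}.meta.json"
        fsio.write_session_meta(bundle.meta, meta_path)
        ann_path = out / f"{sid}.annotations.csv"
        fsio.write_annotations(perfect_rater_annotations(bundle.frames), ann_path)
        written += [meta_path, ann_path]
        for provider_id, dialect in dialect_of.items():
            vecs = [v for v in bundle.vectors if v.provider_id == provider_id]
            score_path = out / f"{sid}.scores.{provider_id}.jsonl"
            fsio.write_provider_scores(vecs, score_path, dialect)
            written.append(score_path)
    return written
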