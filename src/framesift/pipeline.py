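"""Dataset loading and the five extraction techniques, end to end.

The techniques compared throughout:

* ``entire_video`` — an emotion's prevalence over all ground-truth frames;
* ``boundary`` — frames inside matching prompt regions;
* ``subbound`` — boundary frames after the optimized (alpha, beta) trim;
* ``subbound_minconf`` — sub-bound plus the optimized single-provider
  minimum-confidence filter;
* ``subbound_ensemble`` — sub-bound plus the filter on fused scores from
  all providers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import io as fsio
from .agreement import consensus_labels
from .labels import CANONICAL_EMOTIONS, EmotionLabel, LabelMapping, SchemaError, default_mapping
from .models import ConfidenceVector, Frame, FusionMethod, SessionMeta, attach_truth, frame_grid
from .optimize import (
    DEFAULT_ALPHA_MAX,
    DEFAULT_BETA_MAX,
    DEFAULT_LAMBDA_MAX,
    DEFAULT_LAMBDA_STEP,
    DEFAULT_TIME_STEP,
    BaselineMode,
    LossDenominator,
    SearchResult,
    optimize_lambda,
    optimize_subbound,
)
from .selection import fused_score_map, single_provider_score_map

TECHNIQUES = (
    "entire_video",
    "boundary",
    "subbound",
    "subbound_minconf",
    "subbound_ensemble",
)


@dataclass(frozen=True)
class LoadedSession:
    meta: SessionMeta
    frames: tuple[Frame, ...]  # true_label filled from rater consensus
    truth: Mapping[str, EmotionLabel]
    vectors: tuple[ConfidenceVector, ...]


@dataclass(frozen=True)
class Dataset:
    sessions: tuple[LoadedSession, ...]
    providers: tuple[str, ...]

    def session_data(self):
        return [(s.meta, s.frames, None) for s in self.sessions]

    def all_vectors(self) -> list[ConfidenceVector]:
        return [v for s in self.sessions for v in s.vectors]

    def all_frames(self) -> list[Frame]:
        return [f for s in self.sessions for f in s.frames]


def load_dataset(
    directory: Union[str, Path],
    mapping: Optional[LabelMapping] = None,
    raters: tuple[str, str] = ("r1", "r2"),
) -> Dataset:
    """Load every session bundle under *directory*.

    Expects ``<sid>.meta.json``, ``<sid>.annotations.csv``,
    ``<sid>.scores.<provider>.jsonl`` and a ``providers.json`` manifest
    naming each provider's score dialect. Ground truth is the two-rater
    consensus of the annotation files.
    """
    mapping = mapping or default_mapping()
    directory = Path(directory)
    manifest_path = directory / "providers.json"
    dialects: dict[str, str] = {}
    if manifest_path.exists():
        dialects = json.loads(manifest_path.read_text(encoding="utf-8"))["providers"]
    meta_paths = sorted(directory.glob("*.meta.json"))
    if not meta_paths:
        raise SchemaError(f"no session meta files under {directory}")
    sessions = []
    providers: set[str] = set()
    for meta_path in meta_paths:
        sid = meta_path.name[: -len(".meta.json")]
        meta = fsio.read_session_meta(meta_path, mapping)
        annotations = fsio.read_annotations(
            directory / f"{sid}.annotations.csv", mapping
        )
        truth, _ = consensus_labels(annotations, raters)
        frames = attach_truth(frame_grid(meta), truth)
        vectors: list[ConfidenceVector] = []
        for score_path in sorted(directory.glob(f"{sid}.scores.*.jsonl")):
            provider = score_path.name[len(sid) + 8 : -len(".jsonl")]
            providers.add(provider)
            vectors.extend(
                fsio.read_provider_scores(score_path, dialects.get(provider, "unit"))
            )
        sessions.append(
            LoadedSession(
                meta=meta, frames=frames, truth=truth, vectors=tuple(vectors)
            )
        )
    return Dataset(sessions=tuple(sessions), providers=tuple(sorted(providers)))


def prevalence(dataset: Dataset, emotion: EmotionLabel) -> float:
    """Entire-video baseline: the emotion's share of all ground-truth frames."""
    labeled = [f for f in dataset.all_frames() if f.true_label is not None]
    if not labeled:
        raise ValueError("dataset has no ground-truth frames")
    return sum(f.true_label is emotion for f in labeled) / len(labeled)


@dataclass(frozen=True)
class EmotionReport:
    emotion: EmotionLabel
    subbound: SearchResult
    minconf: SearchResult
    ensemble: SearchResult


def optimize_emotion(
    dataset: Dataset,
    emotion: EmotionLabel,
    fusion: FusionMethod = FusionMethod.AVERAGE,
    provider: Optional[str] = None,
    time_step: float = DEFAULT_TIME_STEP,
    lambda_step: float = DEFAULT_LAMBDA_STEP,
    alpha_max: float = DEFAULT_ALPHA_MAX,
    beta_max: float = DEFAULT_BETA_MAX,
    lambda_max: float = DEFAULT_LAMBDA_MAX,
    baseline_mode: BaselineMode = "previous",
    loss_denominator: LossDenominator = "matching",
) -> EmotionReport:
    """Sequential per-class optimization: (alpha, beta) first, then lambda
    for a single provider and for the fused ensemble."""
    data = dataset.session_data()
    sub = optimize_subbound(
        data,
        emotion,
        step=time_step,
        alpha_max=alpha_max,
        beta_max=beta_max,
        baseline_mode=baseline_mode,
        loss_denominator=loss_denominator,
    )
    fixed = (sub.params.alpha, sub.params.beta)
    vectors = dataset.all_vectors()
    provider = provider or (dataset.providers[0] if dataset.providers else None)
    if provider is None:
        raise ValueError("no provider scores in the dataset")
    common = dict(
        step=lambda_step,
        lambda_max=lambda_max,
        baseline_mode=baseline_mode,
        loss_denominator=loss_denominator,
    )
    minconf = optimize_lambda(
        data,
        emotion,
        fixed,
        single_provider_score_map(vectors, emotion, provider),
        **common,
    )
    ensemble = optimize_lambda(
        data, emotion, fixed, fused_score_map(vectors, emotion, fusion), **common
    )
    return EmotionReport(emotion=emotion, subbound=sub, minconf=minconf, ensemble=ensemble)


def technique_densities(
    dataset: Dataset,
    emotions: Sequence[EmotionLabel] = CANONICAL_EMOTIONS,
    fusion: FusionMethod = FusionMethod.AVERAGE,
    provider: Optional[str] = None,
    **optimize_kwargs,
) -> pd.DataFrame:
    """Density (percent of retained frames matching the target emotion) per
    emotion per technique; emotions with no regions are reported as NaN."""
    rows = []
    for emotion in emotions:
        row: dict[str, object] = {"emotion": emotion.value}
        try:
            report = optimize_emotion(
                dataset, emotion, fusion=fusion, provider=provider, **optimize_kwargs
            )
        except ValueError:
            rows.append(
                row
                | {t: math.nan for t in TECHNIQUES}
                | {"alpha": math.nan, "beta": math.nan, "lam": math.nan}
            )
            continue
        row["entire_video"] = 100.0 * prevalence(dataset, emotion)
        row["boundary"] = 100.0 * report.subbound.baseline.density
        row["subbound"] = 100.0 * report.subbound.final.density
        row["subbound_minconf"] = 100.0 * report.minconf.final.density
        row["subbound_ensemble"] = 100.0 * report.ensemble.final.density
        row["alpha"] = report.subbound.params.alpha
        row["beta"] = report.subbound.params.beta
        row["lam"] = report.ensemble.params.lam
        rows.append(row)
    return pd.DataFrame(rows)


def parameter_report(
    dataset: Dataset,
    emotions: Sequence[EmotionLabel] = CANONICAL_EMOTIONS,
    fusion: FusionMethod = FusionMethod.AVERAGE,
    provider: Optional[str] = None,
    **optimize_kwargs,
) -> pd.DataFrame:
    """Per-emotion optimal (alpha, beta, lambda) with before/after states."""
    rows = []
    for emotion in emotions:
        try:
            report = optimize_emotion(
                dataset, emotion, fusion=fusion, provider=provider, **optimize_kwargs
            )
        except ValueError as exc:
            rows.append({"emotion": emotion.value, "skipped": str(exc)})
            continue
        rows.append(
            {
                "emotion": emotion.value,
                "alpha": report.subbound.params.alpha,
                "beta": report.subbound.params.beta,
                "lam": report.minconf.params.lam,
                "lam_ensemble": report.ensemble.params.lam,
                "baseline_density": report.subbound.baseline.density,
                "final_density": report.minconf.final.density,
                "baseline_retained": report.subbound.baseline.retained,
                "final_retained": report.minconf.final.retained,
                "skipped": "",
            }
        )
    return pd.DataFrame(rows)
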