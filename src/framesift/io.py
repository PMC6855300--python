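"""Readers and writers for the system's external formats.

Formats (all UTF-8):

* session meta — JSON: ``{session_id, duration_s, fps, regions: [{index,
  emotion, t_start_s, t_end_s, point_awarded}, ...]}``
* rater annotations — CSV with header ``frame_id,rater_id,label``
  (empty label = the rater could not label the frame)
* provider confidence scores — JSON-lines, one record per frame per
  provider: ``{"frame_id": ..., "provider": ..., "scores": {term: number}}``,
  read through a registered *dialect* that declares the provider's score
  range and emotion vocabulary
* framesets — CSV, one row per retained frame with full filter provenance
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import pandas as pd

from .labels import (
    DISCARD,
    EmotionLabel,
    LabelMapping,
    SchemaError,
    VocabularyError,
    default_mapping,
)
from .models import (
    ConfidenceVector,
    Frame,
    FrameSet,
    FusionMethod,
    PromptRegion,
    Provenance,
    RaterAnnotation,
    SelectedFrame,
    SessionMeta,
)

logger = logging.getLogger(__name__)

Source = Union[str, Path, IO[str]]


def _open(source: Source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


# ---------------------------------------------------------------------------
# session meta


def read_session_meta(
    source: Source, mapping: Optional[LabelMapping] = None
) -> SessionMeta:
    """Parse a session-meta JSON document into a validated :class:`SessionMeta`.

    Region emotions are canonicalized through *mapping* (e.g. a ``contempt``
    prompt becomes ``angry``). Overlapping or out-of-range regions raise
    :class:`SchemaError`; emotions that map to DISCARD or are unknown raise
    :class:`VocabularyError`.
    """
    mapping = mapping or default_mapping()
    handle, close = _open(source)
    try:
        doc = json.load(handle)
    finally:
        if close:
            handle.close()
    try:
        session_id = str(doc["session_id"])
        duration = float(doc.get("duration_s", 90.0))
        fps = float(doc.get("fps", 5.0))
        raw_regions = doc["regions"]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed session meta: {exc}") from exc

    regions = []
    for raw in raw_regions:
        label = mapping.canonical(str(raw["emotion"]))
        if label is DISCARD:
            raise VocabularyError(
                f"region emotion {raw['emotion']!r} maps to DISCARD and cannot "
                "name a prompt region"
            )
        regions.append(
            PromptRegion(
                region_index=int(raw["index"]),
                emotion=label,
                t_start=float(raw["t_start_s"]),
                t_end=float(raw["t_end_s"]),
                point_awarded=bool(raw.get("point_awarded", False)),
            )
        )
    return SessionMeta(
        session_id=session_id, regions=tuple(regions), duration=duration, fps=fps
    )


def write_session_meta(session: SessionMeta, sink: Source) -> None:
    doc = {
        "session_id": session.session_id,
        "duration_s": session.duration,
        "fps": session.fps,
        "regions": [
            {
                "index": r.region_index,
                "emotion": r.emotion.value,
                "t_start_s": r.t_start,
                "t_end_s": r.t_end,
                "point_awarded": r.point_awarded,
            }
            for r in session.regions
        ],
    }
    handle, close = _open(sink, "w")
    try:
        json.dump(doc, handle, indent=2, sort_keys=True)
        handle.write("\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# rater annotations


def read_annotations(
    source: Source, mapping: Optional[LabelMapping] = None
) -> list[RaterAnnotation]:
    """Read a rater-annotation CSV, mapping raw labels to canonical ones.

    An empty label cell and any term the mapping marks DISCARD both become
    ``None`` (the frame is unlabelable for that rater). Duplicate
    ``(frame_id, rater_id)`` rows raise :class:`SchemaError`.
    """
    mapping = mapping or default_mapping()
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    required = {"frame_id", "rater_id", "label"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"annotation table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if df.duplicated(subset=["frame_id", "rater_id"]).any():
        dupes = df[df.duplicated(subset=["frame_id", "rater_id"])]
        raise SchemaError(
            f"duplicate (frame_id, rater_id) rows, e.g. {dupes.iloc[0].tolist()}"
        )
    annotations = []
    for row in df.itertuples(index=False):
        raw = row.label.strip()
        if raw == "":
            label: Optional[EmotionLabel] = None
        else:
            mapped = mapping.canonical(raw)
            label = None if mapped is DISCARD else mapped
        annotations.append(
            RaterAnnotation(frame_id=row.frame_id, rater_id=row.rater_id, label=label)
        )
    return annotations


def write_annotations(annotations: Sequence[RaterAnnotation], sink: Source) -> None:
    df = pd.DataFrame(
        {
            "frame_id": [a.frame_id for a in annotations],
            "rater_id": [a.rater_id for a in annotations],
            "label": ["" if a.label is None else a.label.value for a in annotations],
        }
    )
    df.to_csv(sink, index=False)


# ---------------------------------------------------------------------------
# provider confidence-score dialects


@dataclass(frozen=True)
class ScoreDialect:
    """How one provider reports scores: declared range plus vocabulary."""

    name: str
    scale: tuple[float, float]
    vocabulary: LabelMapping

    def normalize(self, value: float) -> float:
        lo, hi = self.scale
        if not (lo - 1e-9 <= value <= hi + 1e-9):
            raise SchemaError(
                f"dialect {self.name!r}: score {value} outside declared "
                f"range [{lo}, {hi}]"
            )
        return (value - lo) / (hi - lo)


_DIALECTS: dict[str, ScoreDialect] = {}


def register_dialect(dialect: ScoreDialect) -> None:
    _DIALECTS[dialect.name] = dialect


def get_dialect(name: str) -> ScoreDialect:
    try:
        return _DIALECTS[name]
    except KeyError:
        raise SchemaError(f"unregistered score dialect: {name!r}") from None


def _register_builtin_dialects() -> None:
    base = default_mapping()
    register_dialect(ScoreDialect("unit", (0.0, 1.0), base))
    register_dialect(ScoreDialect("percent", (0.0, 100.0), base))
    # Cloud-provider response shapes, emulated from their documented keys.
    register_dialect(ScoreDialect("azure", (0.0, 1.0), base))
    register_dialect(ScoreDialect("sighthound", (0.0, 100.0), base))
    register_dialect(ScoreDialect("rekognition", (0.0, 100.0), base))


_register_builtin_dialects()


def read_provider_scores(
    source: Source, dialect: Union[str, ScoreDialect]
) -> list[ConfidenceVector]:
    """Read a provider's JSON-lines score file through a registered dialect.

    Scores are rescaled to [0, 1]; provider emotion names are canonicalized.
    Terms mapped to DISCARD are dropped; unknown terms are ignored with a
    warning (provider APIs add categories over time). Terms that merge onto
    the same canonical label (anger + contempt) are summed and capped at 1.
    Records with missing/null scores (no face found) yield no vector.
    """
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    handle, close = _open(source)
    vectors: list[ConfidenceVector] = []
    seen: set[tuple[str, str]] = set()
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
                frame_id = str(record["frame_id"])
                provider = str(record["provider"])
            except (json.JSONDecodeError, KeyError) as exc:
                raise SchemaError(f"line {lineno}: malformed record: {exc}") from exc
            raw_scores = record.get("scores")
            if raw_scores is None:
                continue  # no face in this frame
            key = (frame_id, provider)
            if key in seen:
                raise SchemaError(
                    f"line {lineno}: duplicate record for frame {frame_id!r} "
                    f"provider {provider!r}"
                )
            seen.add(key)
            scores: dict[EmotionLabel, float] = {}
            for term, value in raw_scores.items():
                if not dialect.vocabulary.contains(term):
                    logger.warning(
                        "dialect %s: ignoring unknown emotion key %r",
                        dialect.name,
                        term,
                    )
                    continue
                mapped = dialect.vocabulary.canonical(term)
                if mapped is DISCARD:
                    continue
                normalized = dialect.normalize(float(value))
                # union of merged categories, capped to keep scores in [0, 1]
                scores[mapped] = min(1.0, scores.get(mapped, 0.0) + normalized)
            vectors.append(
                ConfidenceVector(frame_id=frame_id, provider_id=provider, scores=scores)
            )
    finally:
        if close:
            handle.close()
    return vectors


def write_provider_scores(
    vectors: Iterable[ConfidenceVector],
    sink: Source,
    dialect: Union[str, ScoreDialect] = "unit",
) -> None:
    """Write vectors as JSON-lines in the given dialect's scale."""
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    lo, hi = dialect.scale
    handle, close = _open(sink, "w")
    try:
        for v in vectors:
            record = {
                "frame_id": v.frame_id,
                "provider": v.provider_id,
                "scores": {
                    e.value: lo + s * (hi - lo) for e, s in sorted(v.scores.items())
                },
            }
            handle.write(json.dumps(record, sort_keys=True))
            handle.write("\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# framesets

_FRAMESET_COLUMNS = [
    "session_id",
    "frame_id",
    "timestamp",
    "label",
    "region_index",
    "alpha",
    "beta",
    "lam",
    "fusion",
    "providers",
]


def write_frameset(frameset: FrameSet, sink: Source) -> None:
    """Write one row per retained frame, carrying the full filter provenance."""
    prov = frameset.provenance
    rows = [
        {
            "session_id": frameset.session_id,
            "frame_id": m.frame.frame_id,
            "timestamp": m.frame.timestamp,
            "label": frameset.emotion.value,
            "region_index": m.region_index,
            "alpha": prov.alpha,
            "beta": prov.beta,
            "lam": prov.lam,
            "fusion": prov.fusion.value if prov.fusion else "",
            "providers": "|".join(prov.providers),
        }
        for m in frameset.members
    ]
    df = pd.DataFrame(rows, columns=_FRAMESET_COLUMNS)
    df.to_csv(sink, index=False)


def read_frameset(source: Source) -> FrameSet:
    """Re-read a frameset CSV written by :func:`write_frameset`.

    Ground-truth labels are not part of the on-disk format; re-read frames
    carry ``true_label=None``.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = set(_FRAMESET_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"frameset file missing columns: {sorted(missing)}")
    if df.empty:
        raise SchemaError(
            "cannot reconstruct a frameset from a header-only file: the "
            "session and emotion live only on data rows"
        )
    session_ids = df["session_id"].unique()
    labels = df["label"].unique()
    if len(session_ids) != 1 or len(labels) != 1:
        raise SchemaError("a frameset file holds exactly one session and emotion")
    first = df.iloc[0]
    prov = Provenance(
        alpha=float(first["alpha"]),
        beta=float(first["beta"]),
        lam=float(first["lam"]),
        fusion=FusionMethod(first["fusion"]) if first["fusion"] else None,
        providers=tuple(p for p in first["providers"].split("|") if p),
    )
    members = tuple(
        SelectedFrame(
            frame=Frame(frame_id=row.frame_id, timestamp=float(row.timestamp)),
            region_index=int(row.region_index),
        )
        for row in df.itertuples(index=False)
    )
    return FrameSet(
        session_id=str(session_ids[0]),
        emotion=EmotionLabel(labels[0]),
        members=members,
        provenance=prov,
    )
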