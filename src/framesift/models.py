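"""Core domain records: sessions, prompt regions, frames, scores, framesets.

A game session is a 90-second video whose meta information partitions the
timeline into prompt regions, each with a target emotion. Frames are
abstract timestamped records (subsampled at 5 frames/second by default);
no pixel data enters the system.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .labels import EmotionLabel, SchemaError

#: Slack for floating-point interval comparisons (well below one frame period).
EPS = 1e-9


class FusionMethod(str, enum.Enum):
    """How per-provider confidence scores are combined into one value."""

    MIN = "min"
    MAX = "max"
    AVERAGE = "average"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class PromptRegion:
    """One prompt's on-screen interval ``[t_start, t_end)`` and its emotion."""

    region_index: int
    emotion: EmotionLabel
    t_start: float
    t_end: float
    point_awarded: bool = False

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise SchemaError(
                f"region {self.region_index}: t_start {self.t_start} must be "
                f"< t_end {self.t_end}"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class SessionMeta:
    """Boundary structure of one game session."""

    session_id: str
    regions: tuple[PromptRegion, ...]
    duration: float = 90.0
    fps: float = 5.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise SchemaError("fps must be positive")
        regions = tuple(sorted(self.regions, key=lambda r: r.t_start))
        for r in regions:
            if r.t_start < -EPS or r.t_end > self.duration + EPS:
                raise SchemaError(
                    f"region {r.region_index} [{r.t_start}, {r.t_end}) lies "
                    f"outside the session [0, {self.duration}]"
                )
        for a, b in zip(regions, regions[1:]):
            if b.t_start < a.t_end - EPS:
                raise SchemaError(
                    f"regions {a.region_index} and {b.region_index} overlap"
                )
        object.__setattr__(self, "regions", regions)

    def n_frames(self) -> int:
        return int(math.floor(self.duration * self.fps + EPS))

    def region_at(self, timestamp: float) -> Optional[PromptRegion]:
        """Region containing *timestamp* under the [t_start, t_end) convention."""
        for r in self.regions:
            if r.t_start - EPS <= timestamp < r.t_end - EPS:
                return r
        return None


@dataclass(frozen=True)
class Frame:
    """A timestamped frame with an optional ground-truth label."""

    frame_id: str
    timestamp: float
    true_label: Optional[EmotionLabel] = None

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise SchemaError(f"frame {self.frame_id}: negative timestamp")


def frame_grid(session: SessionMeta) -> tuple[Frame, ...]:
    """The session's frame skeleton: frame *i* at ``i / fps``, no labels."""
    return tuple(
        Frame(frame_id=f"{session.session_id}-f{i:04d}", timestamp=i / session.fps)
        for i in range(session.n_frames())
    )


@dataclass(frozen=True)
class RaterAnnotation:
    """One rater's raw call on one frame; ``label=None`` means unlabelable."""

    frame_id: str
    rater_id: str
    label: Optional[EmotionLabel]


@dataclass(frozen=True)
class ConfidenceVector:
    """One provider's normalized per-emotion confidence scores for one frame."""

    frame_id: str
    provider_id: str
    scores: Mapping[EmotionLabel, float]

    def __post_init__(self) -> None:
        for emotion, value in self.scores.items():
            if not (-EPS <= value <= 1 + EPS):
                raise SchemaError(
                    f"frame {self.frame_id} provider {self.provider_id}: "
                    f"score {value} for {emotion} outside [0, 1]"
                )
        object.__setattr__(self, "scores", dict(self.scores))


@dataclass(frozen=True)
class TrimParams:
    """Per-class filter parameters: leading trim α, trailing trim β (seconds)
    and minimum classification confidence λ."""

    emotion: EmotionLabel
    alpha: float = 0.0
    beta: float = 0.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")


@dataclass(frozen=True)
class Provenance:
    """The filters that produced a frameset."""

    alpha: float = 0.0
    beta: float = 0.0
    lam: float = 0.0
    fusion: Optional[FusionMethod] = None
    providers: tuple[str, ...] = ()


@dataclass(frozen=True)
class SelectedFrame:
    frame: Frame
    region_index: int


@dataclass(frozen=True)
class FrameSet:
    """Frames retained for one emotion in one session, with provenance."""

    session_id: str
    emotion: EmotionLabel
    members: tuple[SelectedFrame, ...]
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        ts = [m.frame.timestamp for m in self.members]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise SchemaError("frameset timestamps must be strictly increasing")

    @property
    def frames(self) -> tuple[Frame, ...]:
        return tuple(m.frame for m in self.members)

    def frame_ids(self) -> tuple[str, ...]:
        return tuple(m.frame.frame_id for m in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def with_members(
        self, members: Iterable[SelectedFrame], **provenance_updates
    ) -> "FrameSet":
        prov = replace(self.provenance, **provenance_updates)
        return FrameSet(
            session_id=self.session_id,
            emotion=self.emotion,
            members=tuple(members),
            provenance=prov,
        )


def attach_truth(
    frames: Sequence[Frame], truth: Mapping[str, EmotionLabel]
) -> tuple[Frame, ...]:
    """Return *frames* with ``true_label`` filled from a frame_id → label map."""
    return tuple(
        replace(f, true_label=truth.get(f.frame_id, f.true_label)) for f in frames
    )
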