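"""Frame selection: region membership, sub-bound trimming, score fusion,
and minimum-confidence filtering.

For a target emotion, the *boundary* selection keeps every frame whose
timestamp falls in a prompt region with that emotion. The *sub-bound*
selection additionally crops alpha seconds at the region start (the child's
interpretation lag) and beta seconds at its end (relaxation / phone-tilt
decay). The *minimum-confidence* filter then keeps only frames whose
classifier confidence for the region's emotion exceeds lambda; confidences
from several providers may first be fused by min, max, or average.

Interval convention: a region owns ``[t_start, t_end)`` and the sub-bound
is ``[t_start + alpha, t_end - beta)``, so a frame on a shared boundary
belongs to exactly one region (the newly shown prompt).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from .labels import EmotionLabel
from .models import (
    EPS,
    ConfidenceVector,
    Frame,
    FrameSet,
    FusionMethod,
    Provenance,
    SelectedFrame,
    SessionMeta,
)


def frames_in_subbound(
    session: SessionMeta,
    frames: Sequence[Frame],
    emotion: EmotionLabel,
    alpha: float = 0.0,
    beta: float = 0.0,
) -> FrameSet:
    """Frames with ``t_start + alpha <= t < t_end - beta`` in matching regions.

    A region whose trimmed interval is empty contributes no frames; an
    emotion with no region yields an empty set. Negative trims are an error.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    members: list[SelectedFrame] = []
    for region in session.regions:
        if region.emotion is not emotion:
            continue
        lo = region.t_start + alpha
        hi = region.t_end - beta
        for frame in frames:
            if lo - EPS <= frame.timestamp < hi - EPS:
                members.append(SelectedFrame(frame=frame, region_index=region.region_index))
    members.sort(key=lambda m: m.frame.timestamp)
    return FrameSet(
        session_id=session.session_id,
        emotion=emotion,
        members=tuple(members),
        provenance=Provenance(alpha=alpha, beta=beta),
    )


def frames_in_region(
    session: SessionMeta, frames: Sequence[Frame], emotion: EmotionLabel
) -> FrameSet:
    """Boundary selection: every frame inside a matching region (no trims)."""
    return frames_in_subbound(session, frames, emotion, alpha=0.0, beta=0.0)


def fuse_scores(
    vectors: Iterable[ConfidenceVector],
    emotion: EmotionLabel,
    method: FusionMethod,
) -> Optional[float]:
    """Combine one frame's per-provider scores for *emotion* into one value.

    Providers that returned no vector for the frame simply do not
    participate; a provider whose vector lacks the emotion contributes 0.
    Returns ``None`` when no provider returned a vector at all.
    """
    values = [v.scores.get(emotion, 0.0) for v in vectors]
    if not values:
        return None
    if method is FusionMethod.MIN:
        return min(values)
    if method is FusionMethod.MAX:
        return max(values)
    return sum(values) / len(values)


def fused_score_map(
    vectors: Iterable[ConfidenceVector],
    emotion: EmotionLabel,
    method: FusionMethod,
) -> dict[str, float]:
    """Per-frame fused score for *emotion* across all providers present."""
    by_frame: dict[str, list[ConfidenceVector]] = {}
    for v in vectors:
        by_frame.setdefault(v.frame_id, []).append(v)
    out: dict[str, float] = {}
    for frame_id, vs in by_frame.items():
        fused = fuse_scores(vs, emotion, method)
        if fused is not None:
            out[frame_id] = fused
    return out


def single_provider_score_map(
    vectors: Iterable[ConfidenceVector], emotion: EmotionLabel, provider_id: str
) -> dict[str, float]:
    return {
        v.frame_id: v.scores.get(emotion, 0.0)
        for v in vectors
        if v.provider_id == provider_id
    }


def confidence_filter(
    frameset: FrameSet,
    scores: Mapping[str, float],
    lam: float,
    fusion: Optional[FusionMethod] = None,
    providers: Sequence[str] = (),
) -> FrameSet:
    """Keep frames whose confidence for the set's emotion exceeds *lam*.

    The comparison is strict (score > lambda). ``lam = 0`` means no
    filtering: every frame is kept, including frames with no score at all.
    For ``lam > 0`` a frame with no score is dropped.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if lam == 0.0:
        members: Iterable[SelectedFrame] = frameset.members
    else:
        members = (
            m
            for m in frameset.members
            if m.frame.frame_id in scores and scores[m.frame.frame_id] > lam
        )
    return frameset.with_members(
        members,
        lam=lam,
        fusion=fusion if fusion is not None else frameset.provenance.fusion,
        providers=tuple(providers) or frameset.provenance.providers,
    )
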