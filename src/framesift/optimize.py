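"""Greedy per-class parameter searches driven by the tradeoff ratio k.

The boundary search starts from (alpha, beta) = (0, 0) and repeatedly
considers widening one trim by one step. Each candidate is scored by

    k = density gain (percentage points) / frame loss (percent)

and a step is accepted while k >= 1: the labeled-frame density must improve
at least as fast as frames are being given up. The minimum-confidence
search raises lambda from 0 in fixed increments under the same rule, at a
fixed (alpha, beta).

Two readings of k are supported. ``baseline_mode`` selects the reference
state (the previous accepted state, default, or the initial one);
``loss_denominator`` selects whether the loss counts all retained frames
or only the *matching* (relevant) ones (default). The defaults are the
combination under which trimming away purely mismatched frames is free
(loss 0, k = +inf) and the search stops as soon as a step stops paying
for itself — the behavior the per-class optima in the source study imply.

Density is measured over frames with a ground-truth label; unlabeled
frames carry no evidence and are excluded from both numerator and
denominator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .labels import EmotionLabel
from .models import EPS, Frame, SessionMeta, TrimParams

#: One frame period at 5 fps; every published alpha/beta optimum is a multiple.
DEFAULT_TIME_STEP = 0.2
#: Every published lambda optimum is a multiple of 0.01.
DEFAULT_LAMBDA_STEP = 0.01
DEFAULT_ALPHA_MAX = 2.4
DEFAULT_BETA_MAX = 2.4
DEFAULT_LAMBDA_MAX = 0.5

BaselineMode = Literal["previous", "initial"]
LossDenominator = Literal["matching", "retained"]

SessionData = tuple[SessionMeta, Sequence[Frame], Optional[Mapping[str, EmotionLabel]]]


@dataclass(frozen=True)
class TradeoffState:
    """Retention state of one filter setting: frame counts and density."""

    retained: int
    matching: int

    def __post_init__(self) -> None:
        if self.retained < 0 or self.matching < 0 or self.matching > self.retained:
            raise ValueError("need 0 <= matching <= retained")

    @property
    def density(self) -> float:
        if self.retained == 0:
            raise ValueError("density undefined for an empty retention state")
        return self.matching / self.retained


def tradeoff_ratio(
    base: TradeoffState,
    cand: TradeoffState,
    loss_denominator: LossDenominator = "retained",
) -> float:
    """k = density gain (pp) / frame loss (%), relative to *base*.

    Conventions: no density gain -> k = 0; a gain with no frame loss
    -> k = +inf.
    """
    if base.retained <= 0:
        raise ValueError("baseline state retains no frames")
    cand_density = cand.matching / cand.retained if cand.retained else 0.0
    gain = 100.0 * (cand_density - base.density)
    if gain <= 1e-12:
        return 0.0
    if loss_denominator == "matching":
        if base.matching == 0:
            return math.inf
        loss = 100.0 * (base.matching - cand.matching) / base.matching
    else:
        loss = 100.0 * (base.retained - cand.retained) / base.retained
    if loss <= 1e-12:
        return math.inf
    return gain / loss


@dataclass(frozen=True)
class GreedyStep:
    """One accepted move of a greedy search, with its k at acceptance."""

    alpha: float
    beta: float
    lam: float
    state: TradeoffState
    k: float


@dataclass(frozen=True)
class SearchResult:
    params: TrimParams
    baseline: TradeoffState
    final: TradeoffState
    path: tuple[GreedyStep, ...]  # accepted steps, baseline first with k=nan


# ---------------------------------------------------------------------------
# frame table: vectorized evaluation substrate


@dataclass(frozen=True)
class _FrameTable:
    """Per-frame offsets and match flags for one emotion, pooled over sessions."""

    frame_ids: np.ndarray  # object
    off_start: np.ndarray  # t - t_start
    off_end: np.ndarray  # t_end - t
    matched: np.ndarray  # bool
    scores: Optional[np.ndarray] = None  # float, NaN = no score

    def state(self, alpha: float, beta: float, lam: float = 0.0) -> TradeoffState:
        mask = (self.off_start >= alpha - EPS) & (self.off_end > beta + EPS)
        if lam > 0.0:
            if self.scores is None:
                raise ValueError("lambda > 0 requires per-frame scores")
            with np.errstate(invalid="ignore"):
                mask &= self.scores > lam
        return TradeoffState(
            retained=int(mask.sum()), matching=int(self.matched[mask].sum())
        )

    def with_scores(self, scores: Mapping[str, float]) -> "_FrameTable":
        values = np.array(
            [scores.get(fid, np.nan) for fid in self.frame_ids], dtype=float
        )
        return _FrameTable(
            frame_ids=self.frame_ids,
            off_start=self.off_start,
            off_end=self.off_end,
            matched=self.matched,
            scores=values,
        )


def build_frame_table(sessions: Sequence[SessionData], emotion: EmotionLabel) -> _FrameTable:
    """Pool every labeled frame inside a matching region across sessions.

    Raises if no session has a region with the target emotion, or if those
    regions contain no ground-truth frames.
    """
    ids: list[str] = []
    off_start: list[float] = []
    off_end: list[float] = []
    matched: list[bool] = []
    any_region = False
    for session, frames, truth in sessions:
        regions = [r for r in session.regions if r.emotion is emotion]
        if not regions:
            continue
        any_region = True
        for region in regions:
            for frame in frames:
                if not (region.t_start - EPS <= frame.timestamp < region.t_end - EPS):
                    continue
                label = (
                    truth.get(frame.frame_id) if truth is not None else frame.true_label
                )
                if label is None:
                    continue  # unlabeled frames carry no evidence
                ids.append(frame.frame_id)
                off_start.append(frame.timestamp - region.t_start)
                off_end.append(region.t_end - frame.timestamp)
                matched.append(label is emotion)
    if not any_region:
        raise ValueError(f"no region with emotion {emotion.value!r} in any session")
    if not ids:
        raise ValueError(
            f"regions for {emotion.value!r} contain no ground-truth frames"
        )
    return _FrameTable(
        frame_ids=np.array(ids, dtype=object),
        off_start=np.array(off_start, dtype=float),
        off_end=np.array(off_end, dtype=float),
        matched=np.array(matched, dtype=bool),
    )


# ---------------------------------------------------------------------------
# greedy searches


def optimize_subbound(
    sessions: Sequence[SessionData],
    emotion: EmotionLabel,
    step: float = DEFAULT_TIME_STEP,
    alpha_max: float = DEFAULT_ALPHA_MAX,
    beta_max: float = DEFAULT_BETA_MAX,
    baseline_mode: BaselineMode = "previous",
    loss_denominator: LossDenominator = "matching",
) -> SearchResult:
    """Greedy (alpha, beta) search for one emotion, pooled across sessions.

    From the current trim, both single-axis widenings are scored by k; the
    larger admissible k wins (ties widen alpha). The search stops when
    neither candidate reaches k >= 1 or the caps are hit.
    """
    table = build_frame_table(sessions, emotion)
    return _greedy_subbound(
        table, emotion, step, alpha_max, beta_max, baseline_mode, loss_denominator
    )


def _greedy_subbound(
    table: _FrameTable,
    emotion: EmotionLabel,
    step: float,
    alpha_max: float,
    beta_max: float,
    baseline_mode: BaselineMode,
    loss_denominator: LossDenominator,
) -> SearchResult:
    baseline = table.state(0.0, 0.0)
    if baseline.retained == 0:
        raise ValueError("baseline retains no frames")
    alpha = beta = 0.0
    current = baseline
    path = [GreedyStep(0.0, 0.0, 0.0, baseline, math.nan)]
    n_alpha = 0
    n_beta = 0
    while True:
        reference = baseline if baseline_mode == "initial" else current
        best: Optional[tuple[float, bool, float, float, TradeoffState]] = None
        for widen_alpha in (True, False):
            a = round((n_alpha + 1) * step, 10) if widen_alpha else alpha
            b = beta if widen_alpha else round((n_beta + 1) * step, 10)
            if a > alpha_max + EPS or b > beta_max + EPS:
                continue
            cand = table.state(a, b)
            k = tradeoff_ratio(reference, cand, loss_denominator)
            if k < 1.0:
                continue
            # strictly larger k required to displace the alpha candidate
            if best is None or k > best[0]:
                best = (k, widen_alpha, a, b, cand)
        if best is None:
            break
        k, widen_alpha, alpha, beta, current = best
        n_alpha += int(widen_alpha)
        n_beta += int(not widen_alpha)
        path.append(GreedyStep(alpha, beta, 0.0, current, k))
    return SearchResult(
        params=TrimParams(emotion=emotion, alpha=alpha, beta=beta, lam=0.0),
        baseline=baseline,
        final=current,
        path=tuple(path),
    )


def optimize_lambda(
    sessions: Sequence[SessionData],
    emotion: EmotionLabel,
    fixed: tuple[float, float],
    scores: Mapping[str, float],
    step: float = DEFAULT_LAMBDA_STEP,
    lambda_max: float = DEFAULT_LAMBDA_MAX,
    baseline_mode: BaselineMode = "previous",
    loss_denominator: LossDenominator = "matching",
) -> SearchResult:
    """Greedy lambda search at a fixed (alpha, beta) trim.

    *scores* maps frame_id to the (single-provider or fused) confidence
    for the target emotion; frames absent from the map are retained at
    lambda = 0 and dropped by any positive lambda.
    """
    alpha, beta = fixed
    if alpha < 0 or beta < 0:
        raise ValueError("fixed trim must be non-negative")
    table = build_frame_table(sessions, emotion).with_scores(scores)
    in_bound = (table.off_start >= alpha - EPS) & (table.off_end > beta + EPS)
    if not np.isfinite(table.scores[in_bound]).any():
        raise ValueError("no scored frames inside the sub-bound")
    baseline = table.state(alpha, beta, 0.0)
    if baseline.retained == 0:
        raise ValueError("fixed trim retains no frames")
    lam = 0.0
    current = baseline
    path = [GreedyStep(alpha, beta, 0.0, baseline, math.nan)]
    i = 0
    while True:
        cand_lam = round((i + 1) * step, 10)
        if cand_lam > lambda_max + EPS:
            break
        cand = table.state(alpha, beta, cand_lam)
        reference = baseline if baseline_mode == "initial" else current
        k = tradeoff_ratio(reference, cand, loss_denominator)
        if k < 1.0:
            break
        lam, current = cand_lam, cand
        path.append(GreedyStep(alpha, beta, lam, current, k))
        i += 1
    return SearchResult(
        params=TrimParams(emotion=emotion, alpha=alpha, beta=beta, lam=lam),
        baseline=baseline,
        final=current,
        path=tuple(path),
    )


# ---------------------------------------------------------------------------
# exhaustive oracle


def exhaustive_grid_oracle(
    sessions: Sequence[SessionData],
    emotion: EmotionLabel,
    alphas: Sequence[float],
    betas: Sequence[float],
    lambdas: Sequence[float] = (0.0,),
    scores: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Brute-force density/retention at every (alpha, beta, lambda) grid point.

    Used to verify greedy-path legality and to render tradeoff surfaces.
    Columns: alpha, beta, lam, retained, matching, density (NaN when the
    point retains nothing).
    """
    if not alphas or not betas or not lambdas:
        raise ValueError("empty grid")
    table = build_frame_table(sessions, emotion)
    if any(l > 0 for l in lambdas):
        if scores is None:
            raise ValueError("lambda values > 0 require per-frame scores")
        table = table.with_scores(scores)
    rows = []
    for alpha, beta, lam in itertools.product(alphas, betas, lambdas):
        st = table.state(alpha, beta, lam)
        rows.append(
            {
                "alpha": alpha,
                "beta": beta,
                "lam": lam,
                "retained": st.retained,
                "matching": st.matching,
                "density": st.density if st.retained else math.nan,
            }
        )
    return pd.DataFrame(rows)
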