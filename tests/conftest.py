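import pytest

from framesift import (
    EmotionLabel,
    Frame,
    PromptRegion,
    SessionMeta,
    SimulationConfig,
    default_mapping,
    simulate_bundle,
)


@pytest.fixture(scope="session")
def mapping():
    return default_mapping()


def make_session(regions, session_id="s", duration=None, fps=5.0):
    """Session from (emotion, t_start, t_end) triples."""
    prs = tuple(
        PromptRegion(region_index=i, emotion=e, t_start=a, t_end=b)
        for i, (e, a, b) in enumerate(regions)
    )
    duration = duration if duration is not None else max(r.t_end for r in prs)
    return SessionMeta(session_id=session_id, regions=prs, duration=duration, fps=fps)


def make_frames(timestamps, labels=None, prefix="f"):
    labels = labels or [None] * len(timestamps)
    return tuple(
        Frame(frame_id=f"{prefix}{i}", timestamp=round(t, 9), true_label=lab)
        for i, (t, lab) in enumerate(zip(timestamps, labels))
    )


def grid_times(t_end, step=0.2, t_start=0.0):
    n = int(round((t_end - t_start) / step))
    return [round(t_start + i * step, 9) for i in range(n)]


@pytest.fixture(scope="session")
def small_bundle():
    """Six default-condition synthetic sessions with provider scores."""
    cfg = SimulationConfig(seed=11)
    return cfg, simulate_bundle(cfg, 6)


@pytest.fixture(scope="session")
def happy_region_session():
    session = make_session([(EmotionLabel.HAPPY, 0.0, 2.0), (EmotionLabel.SAD, 2.0, 4.0)])
    frames = make_frames(grid_times(4.0))
    return session, frames
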