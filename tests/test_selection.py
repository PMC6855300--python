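import pytest
from hypothesis import given, settings, strategies as st

from framesift import (
    ConfidenceVector,
    EmotionLabel,
    FusionMethod,
    confidence_filter,
    frames_in_region,
    frames_in_subbound,
    fuse_scores,
)

from conftest import grid_times, make_frames, make_session

HP, SD, NT = EmotionLabel.HAPPY, EmotionLabel.SAD, EmotionLabel.NEUTRAL


class TestRegionSelection:
    def test_ten_frames_in_two_second_region(self, happy_region_session):
        session, frames = happy_region_session
        fs = frames_in_region(session, frames, HP)
        assert len(fs) == 10
        assert all(0.0 <= f.timestamp < 2.0 for f in fs.frames)

    def test_emotion_with_no_region_is_empty(self, happy_region_session):
        session, frames = happy_region_session
        assert len(frames_in_region(session, frames, EmotionLabel.ANGRY)) == 0

    def test_frame_at_shared_boundary_belongs_to_next_region(
        self, happy_region_session
    ):
        session, frames = happy_region_session
        happy = frames_in_region(session, frames, HP)
        sad = frames_in_region(session, frames, SD)
        assert 2.0 not in [f.timestamp for f in happy.frames]
        assert 2.0 in [f.timestamp for f in sad.frames]


class TestSubboundSelection:
    def test_interval_arithmetic(self):
        session = make_session([(HP, 0.0, 3.0)])
        frames = make_frames(grid_times(3.0))
        fs = frames_in_subbound(session, frames, HP, alpha=0.4, beta=0.6)
        # [0.4, 2.4) at 0.2 s spacing
        assert [f.timestamp for f in fs.frames] == pytest.approx(
            [0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2]
        )

    def test_zero_trims_equal_region_selection(self, happy_region_session):
        session, frames = happy_region_session
        assert (
            frames_in_subbound(session, frames, HP, 0.0, 0.0).frame_ids()
            == frames_in_region(session, frames, HP).frame_ids()
        )

    def test_degenerate_interval_is_empty_not_an_error(self):
        session = make_session([(HP, 0.0, 3.0)])
        frames = make_frames(grid_times(3.0))
        assert len(frames_in_subbound(session, frames, HP, 2.0, 2.0)) == 0

    def test_negative_trims_rejected(self, happy_region_session):
        session, frames = happy_region_session
        with pytest.raises(ValueError):
            frames_in_subbound(session, frames, HP, -0.2, 0.0)

    @settings(max_examples=60, derandomize=True)
    @given(
        alpha=st.floats(0.0, 3.0),
        beta=st.floats(0.0, 3.0),
        delta=st.floats(0.0, 1.0),
    )
    def test_nesting_and_monotonicity(self, alpha, beta, delta):
        session = make_session([(HP, 0.0, 4.0), (SD, 4.0, 6.0), (HP, 6.0, 9.0)])
        frames = make_frames(grid_times(9.0))
        base = frames_in_region(session, frames, HP)
        trimmed = frames_in_subbound(session, frames, HP, alpha, beta)
        deeper = frames_in_subbound(session, frames, HP, alpha + delta, beta + delta)
        assert set(trimmed.frame_ids()) <= set(base.frame_ids())
        assert set(deeper.frame_ids()) <= set(trimmed.frame_ids())


def vec(provider, score, emotion=HP):
    return ConfidenceVector(frame_id="f0", provider_id=provider, scores={emotion: score})


class TestFusion:
    def test_min_max_average(self):
        vectors = [vec("a", 0.2), vec("b", 0.4), vec("c", 0.9)]
        assert fuse_scores(vectors, HP, FusionMethod.MIN) == pytest.approx(0.2)
        assert fuse_scores(vectors, HP, FusionMethod.MAX) == pytest.approx(0.9)
        assert fuse_scores(vectors, HP, FusionMethod.AVERAGE) == pytest.approx(0.5)

    def test_missing_provider_excluded(self):
        vectors = [vec("a", 0.2), vec("b", 0.4)]
        assert fuse_scores(vectors, HP, FusionMethod.AVERAGE) == pytest.approx(0.3)

    def test_no_providers_is_absent(self):
        assert fuse_scores([], HP, FusionMethod.AVERAGE) is None

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=5))
    def test_fusion_ordering(self, scores):
        vectors = [vec(f"p{i}", s) for i, s in enumerate(scores)]
        lo = fuse_scores(vectors, HP, FusionMethod.MIN)
        mid = fuse_scores(vectors, HP, FusionMethod.AVERAGE)
        hi = fuse_scores(vectors, HP, FusionMethod.MAX)
        assert lo <= mid + 1e-12 and mid <= hi + 1e-12


class TestConfidenceFilter:
    def region_set(self):
        session = make_session([(HP, 0.0, 1.0)])
        frames = make_frames(grid_times(1.0))
        return frames_in_region(session, frames, HP)

    def test_lambda_zero_means_no_filtering(self):
        fs = self.region_set()
        assert confidence_filter(fs, {}, 0.0).frame_ids() == fs.frame_ids()

    def test_strictly_greater_than_lambda(self):
        fs = self.region_set()
        scores = {"f0": 0.05, "f1": 0.15, "f2": 0.10}
        kept = confidence_filter(fs, scores, 0.10)
        assert kept.frame_ids() == ("f1",)  # 0.10 itself is not > lambda

    def test_unscored_frames_dropped_by_positive_lambda(self):
        fs = self.region_set()
        assert len(confidence_filter(fs, {}, 0.01)) == 0

    def test_lambda_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            confidence_filter(self.region_set(), {}, 1.5)

    def test_filter_output_nested_and_monotone_in_lambda(self):
        fs = self.region_set()
        scores = {f"f{i}": i / 10 for i in range(5)}
        previous = set(fs.frame_ids())
        for lam in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            kept = set(confidence_filter(fs, scores, lam).frame_ids())
            assert kept <= previous
            previous = kept

    def test_trim_then_filter_equals_filter_then_trim(self):
        session = make_session([(HP, 0.0, 3.0), (HP, 5.0, 8.0)], duration=8.0)
        frames = make_frames(grid_times(8.0))
        scores = {f.frame_id: (0.8 if i % 3 else 0.05) for i, f in enumerate(frames)}
        lam, alpha, beta = 0.1, 0.4, 0.6

        trimmed_first = confidence_filter(
            frames_in_subbound(session, frames, HP, alpha, beta), scores, lam
        )
        prefiltered = [f for f in frames if scores[f.frame_id] > lam]
        filtered_first = frames_in_subbound(session, prefiltered, HP, alpha, beta)
        assert trimmed_first.frame_ids() == filtered_first.frame_ids()

    def test_provenance_records_filters(self):
        fs = confidence_filter(
            self.region_set(),
            {"f1": 0.9},
            0.5,
            fusion=FusionMethod.MIN,
            providers=("a", "b"),
        )
        prov = fs.provenance
        assert (prov.lam, prov.fusion, prov.providers) == (0.5, FusionMethod.MIN, ("a", "b"))
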