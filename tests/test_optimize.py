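import math

import pytest

from framesift import (
    EmotionLabel,
    TradeoffState,
    exhaustive_grid_oracle,
    optimize_lambda,
    optimize_subbound,
    tradeoff_ratio,
)

from conftest import grid_times, make_frames, make_session

HP, SD, NT = EmotionLabel.HAPPY, EmotionLabel.SAD, EmotionLabel.NEUTRAL


class TestTradeoffRatio:
    def test_stated_arithmetic(self):
        base = TradeoffState(retained=100, matching=35)
        cand = TradeoffState(retained=90, matching=36)  # density 0.40
        assert tradeoff_ratio(base, cand) == pytest.approx(0.5)

    def test_second_stated_case(self):
        base = TradeoffState(retained=100, matching=58)
        cand = TradeoffState(retained=80, matching=60)  # density 0.75
        assert tradeoff_ratio(base, cand) == pytest.approx(0.85)

    def test_gain_without_loss_is_infinite(self):
        base = TradeoffState(retained=100, matching=35)
        cand = TradeoffState(retained=100, matching=40)
        assert tradeoff_ratio(base, cand) == math.inf

    def test_no_gain_is_zero(self):
        base = TradeoffState(retained=100, matching=35)
        assert tradeoff_ratio(base, TradeoffState(90, 31)) == 0.0
        assert tradeoff_ratio(base, TradeoffState(0, 0)) == 0.0

    def test_empty_baseline_is_an_error(self):
        with pytest.raises(ValueError):
            tradeoff_ratio(TradeoffState(0, 0), TradeoffState(10, 5))

    def test_matching_loss_denominator(self):
        base = TradeoffState(retained=100, matching=50)
        cand = TradeoffState(retained=80, matching=50)
        assert tradeoff_ratio(base, cand, loss_denominator="matching") == math.inf
        cand2 = TradeoffState(retained=60, matching=45)
        # gain 25 pp, matching loss 10% -> k = 2.5
        assert tradeoff_ratio(base, cand2, loss_denominator="matching") == pytest.approx(2.5)


def single_region_sessions(labels, t_end=3.0, emotion=HP):
    """One session, one region [0, t_end), frames every 0.2 s with *labels*."""
    session = make_session([(emotion, 0.0, t_end)])
    frames = make_frames(grid_times(t_end), labels=labels)
    return [(session, frames, None)]


class TestOptimizeSubbound:
    def test_already_perfect_density_keeps_zero_trims(self):
        sessions = single_region_sessions([HP] * 15)
        result = optimize_subbound(sessions, HP)
        assert (result.params.alpha, result.params.beta) == (0.0, 0.0)
        assert result.final == result.baseline

    def test_hopeless_region_keeps_zero_trims(self):
        sessions = single_region_sessions([SD] * 15)
        result = optimize_subbound(sessions, HP)
        assert (result.params.alpha, result.params.beta) == (0.0, 0.0)

    def test_leading_mismatch_is_trimmed_exactly(self):
        # frames in [0, 0.6) mismatch, the rest match
        labels = [SD if t < 0.6 else HP for t in grid_times(3.0)]
        result = optimize_subbound(single_region_sessions(labels), HP)
        assert result.params.alpha == pytest.approx(0.6)
        assert result.params.beta == pytest.approx(0.0)
        assert result.final.density == 1.0

    def test_greedy_point_matches_oracle_table(self):
        labels = [SD if t < 0.6 else HP for t in grid_times(3.0)]
        sessions = single_region_sessions(labels)
        result = optimize_subbound(sessions, HP)
        grid = [round(0.2 * i, 10) for i in range(13)]
        table = exhaustive_grid_oracle(sessions, HP, grid, grid)
        row = table[
            (table.alpha == result.params.alpha) & (table.beta == result.params.beta)
        ].iloc[0]
        assert row.retained == result.final.retained
        assert row.matching == result.final.matching

    def test_every_accepted_step_has_admissible_ratio(self):
        labels = [
            SD if t < 0.4 else (NT if t >= 2.4 else HP) for t in grid_times(3.0)
        ]
        result = optimize_subbound(single_region_sessions(labels), HP)
        for step in result.path[1:]:
            assert step.k >= 1.0

    def test_no_region_for_emotion_is_an_error(self):
        sessions = single_region_sessions([HP] * 15)
        with pytest.raises(ValueError):
            optimize_subbound(sessions, EmotionLabel.ANGRY)

    def test_no_ground_truth_is_an_error(self):
        sessions = single_region_sessions([None] * 15)
        with pytest.raises(ValueError):
            optimize_subbound(sessions, HP)

    def test_terminates_within_cap_iterations(self):
        labels = [SD] * 7 + [HP] * 8
        result = optimize_subbound(
            single_region_sessions(labels), HP, step=0.2, alpha_max=2.4, beta_max=2.4
        )
        assert len(result.path) - 1 <= (2.4 + 2.4) / 0.2


class TestOptimizeLambda:
    def test_perfectly_separating_scores_need_one_step(self):
        labels = [SD if t < 0.6 else HP for t in grid_times(3.0)]
        sessions = single_region_sessions(labels)
        scores = {
            f.frame_id: (1.0 if f.true_label is HP else 0.0)
            for f in sessions[0][1]
        }
        result = optimize_lambda(sessions, HP, (0.0, 0.0), scores, step=0.01)
        assert result.params.lam == pytest.approx(0.01)
        assert result.final.density == 1.0

    def test_all_matching_needs_no_filtering(self):
        sessions = single_region_sessions([HP] * 15)
        scores = {f.frame_id: 0.9 for f in sessions[0][1]}
        result = optimize_lambda(sessions, HP, (0.0, 0.0), scores)
        assert result.params.lam == 0.0

    def test_lambda_is_a_multiple_of_the_step(self):
        labels = [SD if t < 1.0 else HP for t in grid_times(4.0)]
        sessions = single_region_sessions(labels, t_end=4.0)
        scores = {
            f.frame_id: (0.8 if f.true_label is HP else 0.03 + 0.01 * (i % 3))
            for i, f in enumerate(sessions[0][1])
        }
        result = optimize_lambda(sessions, HP, (0.0, 0.0), scores, step=0.01)
        assert result.params.lam == pytest.approx(round(result.params.lam / 0.01) * 0.01)

    def test_no_scored_frames_is_an_error(self):
        sessions = single_region_sessions([HP] * 15)
        with pytest.raises(ValueError):
            optimize_lambda(sessions, HP, (0.0, 0.0), {})

    def test_density_never_drops_when_a_step_is_accepted(self):
        labels = [SD if t < 1.0 else HP for t in grid_times(4.0)]
        sessions = single_region_sessions(labels, t_end=4.0)
        scores = {
            f.frame_id: (0.9 if f.true_label is HP else 0.02)
            for f in sessions[0][1]
        }
        result = optimize_lambda(sessions, HP, (0.0, 0.0), scores)
        densities = [s.state.density for s in result.path]
        assert all(b >= a for a, b in zip(densities, densities[1:]))


class TestExhaustiveOracle:
    def test_single_point_grid_equals_baseline(self):
        labels = [SD if t < 0.6 else HP for t in grid_times(3.0)]
        sessions = single_region_sessions(labels)
        table = exhaustive_grid_oracle(sessions, HP, [0.0], [0.0])
        baseline = optimize_subbound(sessions, HP).baseline
        assert table.iloc[0].retained == baseline.retained
        assert table.iloc[0].matching == baseline.matching

    def test_retained_monotone_along_each_axis(self):
        labels = [SD if t < 0.6 else HP for t in grid_times(3.0)]
        sessions = single_region_sessions(labels)
        grid = [round(0.2 * i, 10) for i in range(8)]
        table = exhaustive_grid_oracle(sessions, HP, grid, grid)
        for beta, group in table.groupby("beta"):
            assert group.sort_values("alpha").retained.is_monotonic_decreasing
        for alpha, group in table.groupby("alpha"):
            assert group.sort_values("beta").retained.is_monotonic_decreasing

    def test_empty_grid_is_an_error(self):
        sessions = single_region_sessions([HP] * 15)
        with pytest.raises(ValueError):
            exhaustive_grid_oracle(sessions, HP, [], [0.0])

    def test_lambda_grid_requires_scores(self):
        sessions = single_region_sessions([HP] * 15)
        with pytest.raises(ValueError):
            exhaustive_grid_oracle(sessions, HP, [0.0], [0.0], lambdas=[0.0, 0.1])
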