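"""Qualifying frames, bout detection, motor activity, session summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from freezescore.classify import (
    BoutConfig,
    FreezingBout,
    PosteriorTrace,
    detect_bouts,
    motor_activity,
    qualifying_frames,
    score_cutoff,
    summarize_session,
)
from freezescore.errors import ConsistencyError, InputError
from freezescore.mixture import MixtureModel
from freezescore.trace import SimilarityTrace


def _post(motion, ambiguous, freezing, fps=30.0):
    probs = np.column_stack([motion, ambiguous, freezing])
    return PosteriorTrace(probs=probs, fps=fps)


def _uniform_post(n, freezing_p, fps=30.0):
    rest = (1.0 - freezing_p) / 2.0
    return _post(np.full(n, rest), np.full(n, rest), np.full(n, freezing_p), fps)


@pytest.fixture(scope="module")
def toy_model():
    return MixtureModel(
        weights=np.array([0.3, 0.3, 0.4]),
        means=np.array([0.955, 0.975, 0.995]),
        sds=np.array([0.004, 0.004, 0.002]),
    )


class TestBoutDetection:
    def test_worked_two_bout_example(self):
        # 4 s of stillness, movement, then 10 s of stillness at 30 fps
        flags = np.concatenate(
            [np.ones(120, bool), np.zeros(30, bool), np.ones(300, bool)]
        )
        bouts = detect_bouts(flags, fps=30.0)
        assert len(bouts) == 2
        assert bouts[0].duration_s == pytest.approx(4.0)
        assert bouts[1].duration_s == pytest.approx(10.0)

    def test_89_frame_run_is_not_freezing(self):
        assert detect_bouts(np.ones(89, bool), fps=30.0) == []

    def test_exact_90_frame_run_is_one_bout(self):
        bouts = detect_bouts(np.ones(90, bool), fps=30.0)
        assert len(bouts) == 1 and bouts[0].duration_s == pytest.approx(3.0)

    def test_all_true_180_frames(self):
        bouts = detect_bouts(np.ones(180, bool), fps=30.0)
        assert len(bouts) == 1 and bouts[0].duration_s == pytest.approx(6.0)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=600))
    def test_bouts_disjoint_ordered_and_floored(self, flags):
        flags = np.array(flags, bool)
        bouts = detect_bouts(flags, fps=30.0, cfg=BoutConfig(min_bout_frames=90))
        prev_end = -1
        for b in bouts:
            assert b.n_frames >= 90
            assert b.start_index > prev_end
            assert flags[b.start_index : b.end_index + 1].all()
            # maximality: neighbors are False or out of range
            if b.start_index > 0:
                assert not flags[b.start_index - 1]
            if b.end_index < flags.size - 1:
                assert not flags[b.end_index + 1]
            prev_end = b.end_index


class TestQualifyingFrames:
    def test_score_far_above_freezing_mean_qualifies(self, toy_model):
        trace = SimilarityTrace(np.array([0.999]))
        post = _uniform_post(1, 0.999)
        for rule in ("tukey_fence", "upper_quartile"):
            flags = qualifying_frames(
                post, toy_model, trace, BoutConfig(quantile_rule=rule)
            )
            assert flags[0]

    def test_upper_quartile_variant_rejects_score_at_freezing_mean(self, toy_model):
        trace = SimilarityTrace(np.array([toy_model.means[2]]))
        post = _uniform_post(1, 0.999)
        cfg = BoutConfig(quantile_rule="upper_quartile")
        assert not qualifying_frames(post, toy_model, trace, cfg)[0]
        # the cut sits exactly at the component's 75th percentile
        expected = toy_model.means[2] + norm.ppf(0.75) * toy_model.sds[2]
        assert score_cutoff(toy_model, cfg) == pytest.approx(expected)

    def test_default_rule_matches_brute_force(self, toy_model):
        rng = np.random.default_rng(8)
        scores = np.clip(rng.normal(0.98, 0.015, 500), 0, 1)
        pf = rng.uniform(0, 1, 500)
        post = _post((1 - pf) / 2, (1 - pf) / 2, pf)
        cfg = BoutConfig()
        flags = qualifying_frames(post, toy_model, SimilarityTrace(scores), cfg)
        q3 = np.quantile(scores, 0.75)
        q1 = np.quantile(scores, 0.25)
        fence = q1 - 1.5 * (q3 - q1)
        expected = (pf >= 0.95) & (scores >= fence)
        assert np.array_equal(flags, expected)

    def test_length_mismatch_rejected(self, toy_model):
        with pytest.raises(InputError):
            qualifying_frames(
                _uniform_post(3, 0.99), toy_model, SimilarityTrace(np.full(4, 0.99))
            )


class TestMotorActivity:
    def test_all_motion_sums_to_length(self):
        post = _post(np.ones(100), np.zeros(100), np.zeros(100))
        assert motor_activity(post) == pytest.approx(100.0)

    def test_no_motion_sums_to_zero(self):
        assert motor_activity(_uniform_post(50, 1.0)) == pytest.approx(0.0)

    def test_matches_brute_force_sum(self, rng):
        m = rng.dirichlet(np.ones(3), size=200)
        post = PosteriorTrace(probs=m)
        assert motor_activity(post) == pytest.approx(float(m[:, 0].sum()), abs=1e-9)


class TestSessionSummary:
    def test_worked_two_bout_summary(self):
        bouts = [FreezingBout(0, 119, 30.0), FreezingBout(150, 449, 30.0)]
        s = summarize_session(bouts, _uniform_post(600, 0.5))
        assert s.total_freezing_s == pytest.approx(14.0)
        assert s.n_bouts == 2
        assert s.mean_bout_s == pytest.approx(7.0)
        assert s.mean_bout_s * s.n_bouts == pytest.approx(s.total_freezing_s)

    def test_no_bouts(self):
        s = summarize_session([], _uniform_post(100, 0.1))
        assert (s.total_freezing_s, s.n_bouts, s.mean_bout_s) == (0.0, 0, 0.0)

    def test_full_session_bout_gives_unit_fraction(self):
        s = summarize_session([FreezingBout(0, 99, 30.0)], _uniform_post(100, 0.99))
        assert s.freezing_fraction == pytest.approx(1.0)

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ConsistencyError):
            summarize_session(
                [FreezingBout(0, 100, 30.0), FreezingBout(50, 200, 30.0)],
                _uniform_post(300, 0.5),
            )

    def test_out_of_bounds_bout_rejected(self):
        with pytest.raises(ConsistencyError):
            summarize_session([FreezingBout(0, 150, 30.0)], _uniform_post(100, 0.5))


class TestEndToEndMonotonicity:
    def test_total_freezing_never_increases_with_stricter_posterior(
        self, sim_results
    ):
        totals = []
        for thr in (0.6, 0.8, 0.95, 0.99):
            cfg = BoutConfig(posterior_threshold=thr)
            flags = qualifying_frames(
                sim_results.posteriors,
                sim_results.mixture,
                sim_results.denoised_trace,
                cfg,
            )
            bouts = detect_bouts(flags, 30.0, cfg)
            totals.append(sum(b.duration_s for b in bouts))
        assert all(a >= b for a, b in zip(totals, totals[1:]))
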