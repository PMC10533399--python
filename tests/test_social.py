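"""Social/identity modulation: labels, windows, GLM, scores, controls."""

import numpy as np
import pytest

from batcolony.social import (
    fraction_same,
    find_optimal_window,
    label_flights_social,
    leading_following_test,
    modulation_scores,
    reward_response_test,
    social_position_test,
    stepwise_social_glm,
    target_bat_analysis,
)
from batcolony.synthetic import (
    CellSpec,
    SpikeTrain,
    make_matched_flightset,
    sample_spikes,
    simulate_cell_rate,
)


@pytest.fixture(scope="module")
def planted_social(matched_flights):
    sess = matched_flights
    mask = sess.truth["flight_social_label"] == "social"
    spec = CellSpec("social", 0.4, 0.0, (0.0, 0.0), 0.5, 4.0, "takeoff", 0.5)
    spikes = sample_spikes(simulate_cell_rate(sess, spec, 0), seed=21)
    return sess, mask, spikes


class TestLabels:
    def test_threshold_classes(self, session900):
        labels = label_flights_social(session900.flights, session900.tracks)
        for lab in labels:
            if lab.nn_distance < 0.6:
                assert lab.label == "social"
            elif lab.nn_distance > 0.9:
                assert lab.label == "non_social"
            else:
                assert lab.label == "ambiguous"

    def test_matches_generator_truth(self, session900):
        labels = label_flights_social(session900.flights, session900.tracks)
        got = np.array([l.label for l in labels])
        np.testing.assert_array_equal(got, session900.truth["flight_social_label"])


class TestOptimalWindow:
    def test_finds_planted_post_takeoff_difference(self, matched_flights, rng):
        sess = matched_flights
        mask = sess.truth["flight_social_label"] == "social"
        # spikes only in [0, 0.5] s after take-off of social flights
        times = np.sort(np.concatenate([
            f.t_takeoff + rng.uniform(0, 0.5, 4)
            for f, m in zip(sess.flights, mask) if m
        ]))
        win = find_optimal_window(SpikeTrain(times), sess.flights, mask, "takeoff")
        assert win.significant
        assert -0.25 <= win.centre <= 0.75  # window overlaps [0, 0.5]

    def test_landing_priority_prefers_pre_windows(self, matched_flights, rng):
        sess = matched_flights
        mask = sess.truth["flight_social_label"] == "social"
        # differences both before and after landing
        times = np.sort(np.concatenate(
            [f.t_land + rng.uniform(-0.8, 0.8, 6)
             for f, m in zip(sess.flights, mask) if m]
        ))
        win = find_optimal_window(SpikeTrain(times), sess.flights, mask, "landing")
        assert win.centre <= -0.25 + 1e-9  # entirely pre-landing

    def test_label_independent_cell_calibrated(self, matched_flights, rng):
        sess = matched_flights
        mask = sess.truth["flight_social_label"] == "social"
        hits = 0
        n = 100
        for k in range(n):
            times = np.sort(rng.uniform(0, sess.duration, 600))
            win = find_optimal_window(SpikeTrain(times), sess.flights, mask,
                                      "takeoff", bonferroni=True)
            hits += win.significant
        assert hits / n <= 0.10  # Bonferroni over correlated windows: <= alpha


class TestStepwiseGLM:
    def test_social_only_dependence_retained(self, rng):
        n = 60
        soc = np.r_[np.ones(30), np.zeros(30)]
        x, y = rng.normal(2.5, 0.3, n), rng.normal(2.5, 0.3, n)
        counts = rng.poisson(np.where(soc > 0, 3.0, 1.0))
        res = stepwise_social_glm(counts, x, y, soc)
        assert res["social_retained"]
        assert res["p_social"] < 0.05

    def test_position_only_dependence_excludes_social(self, rng):
        retained = 0
        for k in range(30):
            r = np.random.default_rng(k)
            n = 60
            soc = r.permutation(np.r_[np.ones(30), np.zeros(30)])
            x, y = r.normal(0, 1.0, n), r.normal(0, 1.0, n)
            counts = r.poisson(np.exp(0.7 + 0.8 * x))
            retained += stepwise_social_glm(counts, x, y, soc)["social_retained"]
        assert retained / 30 <= 0.10

    def test_constant_counts_intercept_only(self):
        n = 40
        res = stepwise_social_glm(np.full(n, 2), np.zeros(n), np.zeros(n),
                                  np.r_[np.ones(20), np.zeros(20)])
        assert res["terms"] == []


class TestPositionTest:
    def test_planted_cell_flagged_without_confound(self, planted_social):
        sess, mask, spikes = planted_social
        res = social_position_test(spikes, sess.flights, mask, sess.tracks[0],
                                   "takeoff", seed=1)
        assert res is not None
        assert res["firing_significant"]
        assert not res["position_significant"]

    def test_systematic_offset_flags_position(self, planted_social):
        sess, mask, spikes = planted_social
        track = sess.tracks[0]
        shifted = type(track)(track.bat_id, track.t, track.pos.copy(),
                              track.accel_mag, track.heading, track.flight_mask)
        # move the bat 0.5 m in x around social take-offs only
        for f, m in zip(sess.flights, mask):
            if m:
                i0 = int((f.t_takeoff - 1.5) * 100)
                i1 = int((f.t_takeoff + 1.5) * 100)
                shifted.pos[i0:i1, 0] += 0.5
        res = social_position_test(spikes, sess.flights, mask, shifted,
                                   "takeoff", seed=2)
        assert res is not None and res["position_significant"]

    def test_too_few_flights_not_analysable(self, planted_social):
        sess, mask, spikes = planted_social
        few = mask.copy()
        few[np.flatnonzero(mask)[4:]] = False  # keep 4 social flights
        keep = few | ~mask
        flights = [f for f, k in zip(sess.flights, keep) if k]
        res = social_position_test(spikes, flights, few[keep], sess.tracks[0],
                                   "takeoff")
        assert res is None


class TestModulationScores:
    def test_planted_social_cell_flagged(self, planted_social):
        sess, mask, spikes = planted_social
        res = modulation_scores(spikes, sess.flights, mask, sess.tracks[0],
                                "takeoff", seed=3)
        assert res is not None
        assert res.scores["firing"] > 0.5
        assert res.scores["position"] < 0.5
        assert res.scores["acceleration"] < 0.5

    def test_sign_convention_social_minus_nonsocial(self, planted_social):
        sess, mask, spikes = planted_social
        res = modulation_scores(spikes, sess.flights, mask, sess.tracks[0],
                                "takeoff", seed=4)
        assert res.modulation_value > 0  # cell fires more on social flights

    def test_null_cell_low_scores(self, matched_flights, rng):
        sess = matched_flights
        mask = sess.truth["flight_social_label"] == "social"
        spikes = SpikeTrain(np.sort(rng.uniform(0, sess.duration, 3000)))
        res = modulation_scores(spikes, sess.flights, mask, sess.tracks[0],
                                "landing", seed=5)
        assert res is not None and not res.significant

    def test_score_order_invariance(self, planted_social):
        sess, mask, spikes = planted_social
        order = np.random.default_rng(6).permutation(len(sess.flights))
        flights = [sess.flights[i] for i in order]
        a = modulation_scores(spikes, sess.flights, mask, sess.tracks[0],
                              "takeoff", seed=7)
        b = modulation_scores(spikes, flights, mask[order], sess.tracks[0],
                              "takeoff", seed=7)
        assert a.scores["firing"] == pytest.approx(b.scores["firing"], abs=0.15)
        assert a.significant == b.significant


class TestTargetBat:
    def test_gating_bat_identified(self, matched_flights):
        sess = matched_flights
        spec = CellSpec("social", 0.4, 0.0, (0.0, 0.0), 0.5, 4.0, "takeoff", 0.5)
        spikes = sample_spikes(simulate_cell_rate(sess, spec, 0), seed=22)
        out = target_bat_analysis(spikes, sess.flights,
                                  sess.truth["flight_per_bat_distance"],
                                  sess.tracks[0], "takeoff", seed=8)
        assert 1 in out["results"]  # bat 1 is the only conspecific
        assert out["results"][1].significant

    def test_fraction_same_properties(self):
        a = np.array([1, 1, 0, 0, -1])
        b = np.array([1, 0, 0, 1, 1])
        assert fraction_same(a, b) == pytest.approx(0.5)
        assert fraction_same(a, b) == fraction_same(b, a)
        assert fraction_same(a, a) == 1.0

    def test_insufficient_flights_skipped(self, matched_flights):
        sess = matched_flights
        d = sess.truth["flight_per_bat_distance"].copy()
        d[4:, 1] = 5.0  # only 4 flights to target for bat 1
        spikes = SpikeTrain(np.sort(np.random.default_rng(9).uniform(0, sess.duration, 500)))
        out = target_bat_analysis(spikes, sess.flights, d, sess.tracks[0], "takeoff")
        assert 1 not in out["results"]


class TestRewardControls:
    def test_planted_follower_detected(self, rng):
        landings = np.sort(rng.uniform(0, 3600, 40))
        follow = landings + rng.uniform(1, 5, 40)
        p = leading_following_test(landings, follow, 3600.0, seed=1)
        assert p is not None and p < 0.05

    def test_independent_schedules_calibrated(self):
        rejections = 0
        tested = 0
        for k in range(100):
            r = np.random.default_rng(k)
            landings = np.sort(r.uniform(0, 3600, 50))
            takeoffs = np.sort(r.uniform(0, 3600, 50))
            p = leading_following_test(landings, takeoffs, 3600.0, seed=k)
            if p is not None:
                tested += 1
                rejections += p < 0.05
        assert tested > 50
        assert rejections / tested <= 0.12

    def test_few_short_intervals_ineligible(self, rng):
        landings = np.array([100.0, 500.0, 900.0])
        takeoffs = landings + 3.0
        assert leading_following_test(landings, takeoffs, 3600.0) is None

    def test_reward_bump_detected_and_null_calibrated(self, rng):
        landings_r = np.arange(10.0, 310.0, 30.0)
        landings_u = np.arange(20.0, 320.0, 30.0)
        spikes = np.sort(np.concatenate(
            [t + rng.uniform(1.0, 2.0, 6) for t in landings_r]
            + [np.array([t + 1.5]) for t in landings_u]
        ))
        res = reward_response_test(SpikeTrain(spikes), landings_r, landings_u, seed=1)
        assert res is not None and res["significant"]
        assert reward_response_test(SpikeTrain(spikes), landings_r[:4],
                                    landings_u) is None
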