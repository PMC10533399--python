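"""Generator contracts: behaviour, cell model, spikes, accelerometer, audio."""

import numpy as np
import pytest
from scipy.signal import periodogram

from batcolony.synthetic import (
    G_ACC,
    CellSpec,
    SessionConfig,
    click_template,
    generate_click_audio,
    generate_group_session,
    sample_spikes,
    simulate_cell_rate,
)


class TestSessionConfig:
    def test_rejects_bad_configs(self):
        with pytest.raises(ValueError):
            SessionConfig(n_bats=1)
        with pytest.raises(ValueError):
            SessionConfig(duration=0)
        with pytest.raises(ValueError):
            SessionConfig(preference_matrix=np.ones((5, 5)))

    def test_cellspec_invariants(self):
        with pytest.raises(ValueError):
            CellSpec("spatial", lam_s=1.0)
        with pytest.raises(ValueError):
            CellSpec("social", lam_c=1.0)
        with pytest.raises(ValueError):
            CellSpec("conjunctive", lam_c=8.0, lam_s=4.0)
        # conjunctive with |lam_s| = lam_c is fine, including suppression
        CellSpec("conjunctive", lam_c=4.0, lam_s=-4.0)


class TestBehaviourGenerator:
    def test_default_rate_gives_many_flights(self, session900):
        # 77 flights/h over 15 min -> ~19 per bat; require a safe lower bound
        for b in range(session900.n_bats):
            assert len(session900.flights_of(b)) >= 5

    def test_hour_session_exceeds_twenty_flights_per_bat(self):
        s = generate_group_session(SessionConfig(n_bats=5, duration=3600.0, seed=4))
        for b in range(5):
            assert len(s.flights_of(b)) >= 20

    def test_deterministic_given_seed(self):
        cfg = dict(n_bats=4, duration=120.0)
        a = generate_group_session(SessionConfig(seed=7, **cfg))
        b = generate_group_session(SessionConfig(seed=7, **cfg))
        for ta, tb in zip(a.tracks, b.tracks):
            np.testing.assert_array_equal(ta.pos, tb.pos)
            np.testing.assert_array_equal(ta.accel_mag, tb.accel_mag)
        assert len(a.flights) == len(b.flights)

    def test_positions_inside_room(self, session900):
        room = np.asarray(session900.config.room)
        for tr in session900.tracks:
            assert (tr.pos >= -0.1).all()
            assert (tr.pos <= room + 0.1).all()

    def test_truth_covers_every_flight(self, session900):
        n = len(session900.flights)
        truth = session900.truth
        assert truth["flight_nn_distance"].shape == (n,)
        assert truth["flight_social_label"].shape == (n,)
        assert truth["flight_per_bat_distance"].shape == (n, session900.n_bats)

    def test_flight_kinematics_realistic(self, session900):
        for f in session900.flights[:30]:
            assert 0.9 <= f.duration <= 4.1
            speed = np.linalg.norm(np.diff(f.path, axis=0), axis=1) * 100.0
            assert speed.max() <= 5.0


class TestCellModel:
    def test_rate_at_field_centre_mid_flight(self, session900):
        f = session900.flights_of(0)[0]
        mid_t = 0.5 * (f.t_takeoff + f.t_land)
        k = int(mid_t / 0.2)  # the 200 ms bin containing mid-flight
        centre_xy = session900.tracks[0].pos_at((k + 0.5) * 0.2)[0, :2]
        spec = CellSpec("spatial", 0.4, 8.0, tuple(centre_xy), 0.5, 0.0,
                        "landing", 0.5)
        rate = simulate_cell_rate(session900, spec, 0)
        assert rate[k] == pytest.approx(8.4, abs=1e-6)  # lam_spont + lam_c

    def test_rest_far_from_flights_is_baseline(self, session900):
        spec = CellSpec("social", 0.4, 0.0, (2.0, 2.0), 0.5, 4.0, "landing", 0.5)
        rate = simulate_cell_rate(session900, spec, 0)
        flights = session900.flights_of(0)
        centres = (np.arange(rate.size) + 0.5) * 0.2
        far = np.ones(rate.size, bool)
        for f in flights:
            far &= (centres < f.t_takeoff - 3.0) | (centres > f.t_land + 3.0)
        assert np.allclose(rate[far], 0.4)

    def test_social_gate_off_gives_baseline(self, matched_flights):
        sess = matched_flights
        spec = CellSpec("social", 0.4, 0.0, (0.0, 0.0), 0.5, 4.0, "landing", 0.5)
        rate = simulate_cell_rate(sess, spec, 0)
        nonsocial = sess.truth["flight_social_label"] == "non_social"
        for f, ns in zip(sess.flights, nonsocial):
            if ns:
                k = int(f.t_land / 0.2)
                assert np.allclose(rate[max(0, k - 3): k + 3], 0.4)

    def test_conjunctive_rate_is_sum_of_terms(self, matched_flights):
        """lam(t) for a conjunctive cell equals its spatial term plus its
        spatially gated social term, recomputed independently."""
        sess = matched_flights
        x_c = tuple(sess.flights[0].p_land[:2])
        conj = CellSpec("conjunctive", 0.4, 4.0, x_c, 0.5, 4.0, "landing", 0.5)
        spat = CellSpec("spatial", 0.4, 4.0, x_c, 0.5, 0.0, "landing", 0.5)
        r_conj = simulate_cell_rate(sess, conj, 0)
        r_spat = simulate_cell_rate(sess, spat, 0)
        social_part = r_conj - r_spat
        # gated social term must be non-negative and bounded by lam_s
        assert social_part.min() >= -1e-9
        assert social_part.max() <= 4.0 + 1e-9
        # and vanish outside the spatial field
        track = sess.tracks[0]
        centres = (np.arange(r_conj.size) + 0.5) * 0.2
        xy = track.pos_at(np.minimum(centres, track.t[-1]))[:, :2]
        outside = np.sum((xy - np.asarray(x_c)) ** 2, axis=1) > 0.5**2
        assert np.allclose(social_part[outside], 0.0)


class TestSampleSpikes:
    def test_zero_rate_gives_empty_train(self):
        assert len(sample_spikes(np.zeros(100), seed=0)) == 0

    def test_poisson_concentration(self):
        n = len(sample_spikes(np.full(5000, 5.0), seed=1))  # 1000 s at 5 Hz
        assert abs(n - 5000) < 3 * np.sqrt(5000)

    def test_deterministic(self):
        r = np.full(50, 3.0)
        np.testing.assert_array_equal(
            sample_spikes(r, seed=3).times, sample_spikes(r, seed=3).times
        )

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sample_spikes(np.array([-1.0]))


class TestAccelerometer:
    def test_rest_deviation_below_threshold(self, session900):
        tr = session900.tracks[0]
        # rest samples away from grooming bouts: check the bulk quantile
        rest = ~tr.flight_mask
        dev = np.abs(tr.accel_mag[rest] - G_ACC)
        assert np.quantile(dev, 0.95) < 0.03
        assert np.mean(tr.accel_mag[rest]) == pytest.approx(G_ACC, abs=0.05)

    def test_flight_spectrum_peaks_at_wingbeat(self, session900):
        tr = session900.tracks[0]
        f = session900.flights_of(0)[0]
        i0 = int(f.t_takeoff * 100) + 5
        i1 = int(f.t_land * 100) - 5
        freqs, pxx = periodogram(tr.accel_mag[i0:i1] - G_ACC, fs=100.0)
        assert abs(freqs[np.argmax(pxx)] - 8.0) < 1.5


class TestClickAudio:
    def test_low_sample_rate_rejected(self, session900):
        with pytest.raises(ValueError):
            generate_click_audio(session900, fs=44100)

    def test_truth_intervals_bimodal(self):
        s = generate_group_session(SessionConfig(n_bats=5, duration=120.0, seed=1))
        _, truth = generate_click_audio(s, seed=2)
        ici = np.diff(truth) * 1000.0
        lo = ici[(ici > 5) & (ici < 60)]
        hi = ici[(ici >= 60) & (ici < 200)]
        assert abs(np.median(lo) - 20) < 4
        assert abs(np.median(hi) - 100) < 15

    def test_no_flights_means_no_clicks(self, session900):
        quiet = type(session900)(
            session900.config, session900.tracks, [], session900.rest_sites,
            session900.truth,
        )
        _, truth = generate_click_audio(quiet, seed=0, rest_click_rate=0.0)
        assert truth.size == 0

    def test_pulse_energy_in_band(self):
        fs = 192000.0
        pulse = click_template(fs)
        spec = np.abs(np.fft.rfft(pulse, n=1 << 14)) ** 2
        freqs = np.fft.rfftfreq(1 << 14, 1 / fs)
        inband = spec[(freqs >= 10e3) & (freqs <= 40e3)].sum()
        assert inband / spec.sum() >= 0.90
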