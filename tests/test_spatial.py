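"""Rate maps, spatial information, Frechet path clustering, 1D fields."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batcolony.spatial import (
    cluster_flight_paths,
    discrete_frechet,
    fit_gaussian_field,
    path_shuffle_test,
    rate_map_1d,
    rate_map_2d,
    resample_path,
    si_bits_per_spike,
    spatial_information,
    spike_shuffle_test,
    split_half_stability,
)
from batcolony.synthetic import (
    BatTrack,
    CellSpec,
    SpikeTrain,
    sample_spikes,
    simulate_cell_rate,
)


def brute_force_si(p, lam):
    mean = np.sum(p * lam)
    total = 0.0
    for pi, li in zip(p, lam):
        if li > 0:
            total += pi * (li / mean) * np.log2(li / mean)
    return total


class TestSpatialInformation:
    @pytest.mark.parametrize(
        "p,lam,expected",
        [
            ([0.5, 0.5], [2.0, 0.0], 1.0),
            ([0.25, 0.75], [4.0, 0.0], 2.0),
            ([0.3, 0.7], [1.5, 1.5], 0.0),
        ],
    )
    def test_closed_forms(self, p, lam, expected):
        assert si_bits_per_spike(np.array(p), np.array(lam)) == pytest.approx(expected)

    def test_matches_brute_force_on_random_maps(self, rng):
        for _ in range(50):
            n = rng.integers(2, 30)
            p = rng.dirichlet(np.ones(n))
            lam = rng.uniform(0, 10, n)
            got = si_bits_per_spike(p, lam)
            assert got == pytest.approx(brute_force_si(p, lam), abs=1e-12)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_rate_rescaling(self, scale):
        p = np.array([0.2, 0.3, 0.5])
        lam = np.array([1.0, 4.0, 0.5])
        assert si_bits_per_spike(p, lam) == pytest.approx(
            si_bits_per_spike(p, scale * lam), abs=1e-10
        )

    def test_zero_mean_rate_flagged(self):
        assert np.isnan(si_bits_per_spike(np.array([1.0]), np.array([0.0])))


def flight_line_track(n=4000, speed=2.0):
    """A bat flying back and forth along y = 2.5 at `speed` m/s."""
    t = np.arange(n) / 100.0
    x = 2.8 + 2.0 * np.sin(2 * np.pi * t / 8.0)
    pos = np.column_stack([x, np.full(n, 2.5), np.ones(n)])
    tr = BatTrack(0, t, pos)
    tr.flight_mask = np.ones(n, bool)
    return tr


class TestRateMap2D:
    def test_zero_spikes_zero_map(self):
        tr = flight_line_track()
        rm = rate_map_2d(tr, SpikeTrain(np.empty(0)))
        assert np.nan_to_num(rm.rate[rm.valid]).max() == 0.0

    def test_single_bin_rate(self):
        # stationary "flight" in one bin: 10 spikes over 2 s -> 5 Hz
        pos = np.tile([1.0, 1.0, 1.0], (200, 1))
        tr = BatTrack(0, np.arange(200) / 100.0, pos)
        tr.flight_mask = np.ones(200, bool)
        spikes = SpikeTrain(np.linspace(0.1, 1.9, 10))
        rm = rate_map_2d(tr, spikes)
        i = np.searchsorted(rm.x_edges, 1.0) - 1
        j = np.searchsorted(rm.y_edges, 1.0) - 1
        assert rm.rate[i, j] == pytest.approx(5.0, rel=1e-6)

    def test_uniform_firing_gives_flat_map(self, rng):
        tr = flight_line_track(8000)
        spikes = SpikeTrain(np.sort(rng.uniform(0, 80, 400)))  # 5 Hz homogeneous
        rm = rate_map_2d(tr, spikes)
        vals = rm.rate[rm.valid & (rm.occupancy > 0.5)]
        assert vals.std() / vals.mean() < 0.5
        assert rm.mean_rate == pytest.approx(5.0, rel=0.25)


class TestShuffleTest:
    def test_planted_place_cell_significant(self, session900, smoothed_track):
        f = session900.flights_of(0)[0]
        mid = f.path[len(f.path) // 2][:2]
        spec = CellSpec("spatial", 0.4, 8.0, tuple(mid), 0.5, 0.0, "landing", 0.5)
        st_ = sample_spikes(simulate_cell_rate(session900, spec, 0), seed=3)
        res = spike_shuffle_test(smoothed_track, st_, n_shuffle=200, seed=4)
        assert res.significant

    def test_homogeneous_cell_rarely_significant(self, smoothed_track, rng):
        flags = []
        dur = smoothed_track.t[-1]
        for k in range(20):
            st_ = SpikeTrain(np.sort(rng.uniform(0, dur, 900)))
            res = spike_shuffle_test(smoothed_track, st_, n_shuffle=100, seed=k)
            flags.append(res.significant)
        assert np.mean(flags) <= 0.25


class TestFrechet:
    @staticmethod
    def brute(a, b):
        from functools import lru_cache

        d = np.linalg.norm(a[:, None] - b[None], axis=2)

        @lru_cache(None)
        def rec(i, j):
            if i == 0 and j == 0:
                return d[0, 0]
            opts = []
            if i > 0:
                opts.append(rec(i - 1, j))
            if j > 0:
                opts.append(rec(i, j - 1))
            if i > 0 and j > 0:
                opts.append(rec(i - 1, j - 1))
            return max(min(opts), d[i, j])

        return rec(len(a) - 1, len(b) - 1)

    def test_matches_exhaustive_couplings(self, rng):
        for _ in range(30):
            a = rng.normal(size=(int(rng.integers(2, 6)), 3))
            b = rng.normal(size=(int(rng.integers(2, 6)), 3))
            assert discrete_frechet(a, b) == pytest.approx(self.brute(a, b), abs=1e-12)

    def test_symmetry_and_identity(self, rng):
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        assert discrete_frechet(a, b) == pytest.approx(discrete_frechet(b, a))
        assert discrete_frechet(a, a) == 0.0


class TestPathClustering:
    def test_identical_flights_one_cluster(self, session900):
        f = session900.flights_of(0)[0]
        clones = [f] * 4
        labels = cluster_flight_paths(clones)
        assert len(set(labels)) == 1

    def test_offset_families_two_clusters(self, session900):
        from batcolony.synthetic import FlightEvent

        f = session900.flights_of(0)[0]
        shifted = FlightEvent(f.bat_id, f.t_takeoff, f.t_land,
                              f.p_takeoff + [3, 0, 0], f.p_land + [3, 0, 0],
                              f.path + [3.0, 0.0, 0.0])
        labels = cluster_flight_paths([f, f, shifted, shifted])
        assert len(set(labels)) == 2
        assert labels[0] == labels[1] and labels[2] == labels[3]

    def test_resample_endpoints_preserved(self, session900):
        f = session900.flights_of(0)[0]
        down = resample_path(f.path, 7)
        assert down.shape == (7, 3)
        np.testing.assert_allclose(down[0], f.path[0])
        np.testing.assert_allclose(down[-1], f.path[-1])


@pytest.fixture(scope="module")
def path_session():
    """A session with only 3 rest sites so flight paths repeat often."""
    from batcolony.synthetic import SessionConfig, generate_group_session
    from batcolony.tracking import smooth_positions

    sess = generate_group_session(
        SessionConfig(n_bats=5, duration=1800.0, n_rest_sites=3, seed=12)
    )
    track = smooth_positions(sess.tracks[0])
    flights = sess.flights_of(0)
    cluster_flight_paths(flights)
    from collections import Counter

    counts = Counter(f.path_cluster for f in flights)

    def path_len(lab):
        f = next(fl for fl in flights if fl.path_cluster == lab)
        return np.sum(np.linalg.norm(np.diff(f.path, axis=0), axis=1))

    # a well-sampled, long path: a field at its midpoint is informative
    lab = max((l for l, n in counts.items() if n >= 8), key=path_len)
    sel = [f for f in flights if f.path_cluster == lab]
    mid = np.asarray(sel[0].path[len(sel[0].path) // 2][:2])
    spec = CellSpec("spatial", 0.4, 8.0, tuple(mid), 0.5, 0.0, "landing", 0.5)
    spikes = sample_spikes(simulate_cell_rate(sess, spec, 0), seed=9)
    # a second, sharper field off-centre along the path (higher 1D contrast)
    pt = np.asarray(sel[0].path[int(len(sel[0].path) * 0.4)][:2])
    narrow = CellSpec("spatial", 0.4, 8.0, tuple(pt), 0.25, 0.0, "landing", 0.5)
    spikes_narrow = sample_spikes(simulate_cell_rate(sess, narrow, 0), seed=9)
    return dict(session=sess, track=track, path=sel, centre=mid, spikes=spikes,
                spikes_narrow=spikes_narrow)


class TestPathMaps:
    def test_exclusion_below_minimum_flights(self, path_session):
        assert rate_map_1d(path_session["path"][:3], path_session["spikes"]) is None

    def test_planted_field_stable_across_halves(self, path_session):
        rho = split_half_stability(path_session["path"],
                                   path_session["spikes_narrow"], seed=11)
        assert rho > 0.5

    def test_planted_field_shuffle_significant(self, path_session):
        res = path_shuffle_test(path_session["path"], path_session["spikes"],
                                n_shuffle=150, seed=12)
        assert res.significant

    def test_uniform_cell_si_within_null(self, path_session, rng):
        sel = path_session["path"]
        uniform = SpikeTrain(np.sort(np.concatenate(
            [rng.uniform(f.t_takeoff, f.t_land, 8) for f in sel]
        )))
        res = path_shuffle_test(sel, uniform, n_shuffle=100, seed=12,
                                min_flights=2, min_spike_flights=1)
        assert not res.significant


class TestFieldFit:
    def test_recovers_planted_parameters(self, path_session):
        rm = rate_map_2d(path_session["track"], path_session["spikes"])
        fit = fit_gaussian_field(rm)
        assert np.linalg.norm(fit["centre"] - path_session["centre"]) < 0.35
        assert abs(fit["sigma"] - 0.5) / 0.5 < 0.5
        assert fit["amplitude"] == pytest.approx(8.0, abs=2.5)
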