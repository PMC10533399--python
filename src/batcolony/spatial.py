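"""Place-field mapping, spatial information and flight-path analysis.

2D occupancy-normalised firing-rate maps over the room footprint (flight
samples only, 0.15 m bins, Gaussian-smoothed spike and occupancy maps),
Skaggs spatial information in bits/spike with circular spike-shuffle
significance, discrete-Frechet clustering of flights into repeated paths,
1D rate maps along rescaled trajectories, and split-half stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.optimize import least_squares
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .synthetic import BatTrack, FlightEvent, SpikeTrain

__all__ = [
    "RateMap2D",
    "PathRateMap",
    "ShuffleResult",
    "rate_map_2d",
    "spatial_information",
    "si_bits_per_spike",
    "spike_shuffle_test",
    "discrete_frechet",
    "resample_path",
    "cluster_flight_paths",
    "rate_map_1d",
    "split_half_stability",
    "path_shuffle_test",
    "fit_gaussian_field",
]

BIN_SIZE = 0.15  # m
SMOOTH_SIGMA = 1.5  # bins
MIN_BIN_OCC = 0.2  # s


@dataclass(eq=False)
class RateMap2D:
    """Occupancy-normalised 2D firing-rate map (flight samples, x-y plane)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy: np.ndarray  # raw seconds per bin
    occupancy_smooth: np.ndarray
    spikes_smooth: np.ndarray
    rate: np.ndarray  # Hz per bin (nan outside smoothed support)
    valid: np.ndarray  # bool

    @property
    def p(self) -> np.ndarray:
        """Occupancy probability per valid bin (sums to 1)."""
        occ = np.where(self.valid, self.occupancy_smooth, 0.0)
        return occ / occ.sum()

    @property
    def mean_rate(self) -> float:
        """lambda-bar = sum_i p_i lambda_i over valid bins."""
        lam = np.where(self.valid, np.nan_to_num(self.rate), 0.0)
        return float((self.p * lam).sum())

    @property
    def peak_location(self) -> np.ndarray:
        r = np.where(self.valid, np.nan_to_num(self.rate), -np.inf)
        i, j = np.unravel_index(np.argmax(r), r.shape)
        xc = 0.5 * (self.x_edges[i] + self.x_edges[i + 1])
        yc = 0.5 * (self.y_edges[j] + self.y_edges[j + 1])
        return np.array([xc, yc])


@dataclass(eq=False)
class PathRateMap:
    """1D firing-rate map along a rescaled repeated flight path."""

    path_cluster_id: int
    bin_centres: np.ndarray  # metres along the mean path
    rate: np.ndarray
    occupancy: np.ndarray
    si: float
    n_flights: int
    n_flights_with_spikes: int


@dataclass(eq=False)
class ShuffleResult:
    si: float
    null: np.ndarray
    significant: bool
    p: float


def rate_map_2d(
    track: BatTrack,
    spikes: SpikeTrain,
    bin_size: float = BIN_SIZE,
    sigma_bins: float = SMOOTH_SIGMA,
    min_occ: float = MIN_BIN_OCC,
    room_xy: tuple[float, float] = (5.6, 5.2),
) -> RateMap2D:
    """2D rate map from flight samples and flight spikes.

    Spike-count and occupancy maps are smoothed with the same Gaussian
    kernel and divided bin by bin; the ratio makes the kernel effectively
    edge-renormalised over the occupied support.  Bins with less than
    ``min_occ`` seconds of raw occupancy are invalidated unless at least one
    of their 8 neighbours is valid.
    """
    fm = track.flight_mask
    if fm is None:
        raise ValueError("track needs a flight_mask")
    dt = 1.0 / track.fs
    nx = max(2, int(np.ceil(room_xy[0] / bin_size)))
    ny = max(2, int(np.ceil(room_xy[1] / bin_size)))
    x_edges = np.linspace(0, room_xy[0], nx + 1)
    y_edges = np.linspace(0, room_xy[1], ny + 1)

    xy = track.pos[fm, :2]
    occ, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[x_edges, y_edges])
    occ *= dt

    # spikes during flight only
    st = spikes.times
    st = st[(st >= track.t[0]) & (st <= track.t[-1])]
    idx = np.clip(np.round((st - track.t[0]) * track.fs).astype(int), 0, track.t.size - 1)
    st = st[fm[idx]]
    sp_pos = track.pos_at(st)[:, :2] if st.size else np.empty((0, 2))
    spk, _, _ = np.histogram2d(sp_pos[:, 0], sp_pos[:, 1], bins=[x_edges, y_edges])

    occ_s = gaussian_filter(occ, sigma_bins, mode="constant")
    spk_s = gaussian_filter(spk, sigma_bins, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ_s > 1e-12, spk_s / np.maximum(occ_s, 1e-12), np.nan)

    base_valid = occ >= min_occ
    # retain an invalid bin if >= 1 of its 8 neighbours is valid
    padded = np.pad(base_valid, 1)
    neigh = np.zeros_like(base_valid)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            neigh |= padded[1 + di : 1 + di + base_valid.shape[0],
                            1 + dj : 1 + dj + base_valid.shape[1]]
    valid = (base_valid | (neigh & (occ > 0))) & np.isfinite(rate)
    return RateMap2D(x_edges, y_edges, occ, occ_s, spk_s, rate, valid)


def si_bits_per_spike(p: np.ndarray, lam: np.ndarray) -> float:
    """Skaggs spatial information: SI = sum_i (p_i lam_i / L) log2(lam_i / L),
    L = sum_i p_i lam_i, with 0 log 0 := 0.  Returns nan when L = 0."""
    p = np.asarray(p, float)
    lam = np.asarray(lam, float)
    mean = float((p * lam).sum())
    if mean <= 0:
        return np.nan
    ratio = lam / mean
    terms = np.where(ratio > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def spatial_information(rate_map: RateMap2D) -> float:
    lam = np.nan_to_num(rate_map.rate[rate_map.valid])
    return si_bits_per_spike(rate_map.p[rate_map.valid], lam)


def _flight_epochs(track: BatTrack) -> np.ndarray:
    fm = track.flight_mask
    edges = np.flatnonzero(np.diff(np.r_[False, fm, False]))
    fs = track.fs
    return np.array(
        [[track.t[s], track.t[s] + (e - s) / fs] for s, e in zip(edges[::2], edges[1::2])]
    ).reshape(-1, 2)


def _to_pseudotime(times: np.ndarray, epochs: np.ndarray):
    """Map event times inside epochs onto the concatenated epoch timeline."""
    durs = epochs[:, 1] - epochs[:, 0]
    offsets = np.concatenate([[0.0], np.cumsum(durs)])
    out = []
    for t in times:
        k = np.searchsorted(epochs[:, 0], t, side="right") - 1
        if k >= 0 and t < epochs[k, 1]:
            out.append(offsets[k] + (t - epochs[k, 0]))
    return np.array(out), float(offsets[-1])


def _from_pseudotime(ptimes: np.ndarray, epochs: np.ndarray) -> np.ndarray:
    durs = epochs[:, 1] - epochs[:, 0]
    offsets = np.concatenate([[0.0], np.cumsum(durs)])
    k = np.clip(np.searchsorted(offsets, ptimes, side="right") - 1, 0, len(durs) - 1)
    return epochs[k, 0] + (ptimes - offsets[k])


def spike_shuffle_test(
    track: BatTrack,
    spikes: SpikeTrain,
    n_shuffle: int = 1000,
    min_shift: float = 10.0,
    seed: int | np.random.Generator | None = 0,
    alpha: float = 0.05,
    **map_kwargs,
) -> ShuffleResult:
    """Significance of 2D spatial information by circular spike shuffling.

    Rest epochs are cut out: spike times are mapped onto the concatenated
    flight timeline, circularly shifted, mapped back, and the map + SI are
    recomputed against the fixed occupancy.  Significant iff the empirical
    SI exceeds the upper (1 - alpha) bound of the null.
    """
    rng = np.random.default_rng(seed)
    epochs = _flight_epochs(track)
    if epochs.size == 0:
        return ShuffleResult(np.nan, np.empty(0), False, 1.0)
    emp_map = rate_map_2d(track, spikes, **map_kwargs)
    si_emp = spatial_information(emp_map)
    ps, span = _to_pseudotime(spikes.times, epochs)
    ms = min(min_shift, span / 4)
    null = np.empty(n_shuffle)
    for k in range(n_shuffle):
        shift = rng.uniform(ms, span - ms)
        shifted = _from_pseudotime(np.sort((ps + shift) % span), epochs)
        null[k] = spatial_information(
            rate_map_2d(track, SpikeTrain(shifted), **map_kwargs)
        )
    null = null[np.isfinite(null)]
    if not np.isfinite(si_emp) or null.size == 0:
        return ShuffleResult(si_emp, null, False, 1.0)
    thresh = np.quantile(null, 1 - alpha)
    p = (1 + int(np.sum(null >= si_emp))) / (null.size + 1)
    return ShuffleResult(si_emp, null, bool(si_emp > thresh), p)


# ---------------------------------------------------------------------------
# flight-path clustering (discrete Frechet)
# ---------------------------------------------------------------------------


def discrete_frechet(a: np.ndarray, b: np.ndarray) -> float:
    """Discrete Frechet distance between two polylines (dynamic program)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]), d[i, j])
    return float(ca[-1, -1])


def resample_path(path: np.ndarray, n_points: int = 7) -> np.ndarray:
    """Spatially downsample a path to ``n_points`` equally spaced in arc
    length; first and last points are the take-off and landing positions."""
    path = np.asarray(path, float)
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.tile(path[0], (n_points, 1))
    target = np.linspace(0, s[-1], n_points)
    out = np.empty((n_points, path.shape[1]))
    for d in range(path.shape[1]):
        out[:, d] = np.interp(target, s, path[:, d])
    return out


def cluster_flight_paths(
    flights: list[FlightEvent],
    n_points: int = 7,
    linkage_cut: float = 1.1,
    method: str = "complete",
) -> np.ndarray:
    """Cluster flights into repeated paths by discrete Frechet distance.

    Paths are downsampled to 7 points; agglomerative clustering (complete
    linkage, so each cluster's internal spread stays below the cut) is cut
    at 1.1 m.  Assigns ``path_cluster`` on each flight and returns labels.
    """
    if not flights:
        return np.empty(0, dtype=int)
    down = [resample_path(f.path, n_points) for f in flights]
    n = len(down)
    if n == 1:
        flights[0].path_cluster = 0
        return np.zeros(1, dtype=int)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = discrete_frechet(down[i], down[j])
    labels = fcluster(linkage(squareform(dm), method=method), t=linkage_cut,
                      criterion="distance") - 1
    for f, lab in zip(flights, labels):
        f.path_cluster = int(lab)
    return labels


# ---------------------------------------------------------------------------
# 1D path rate maps
# ---------------------------------------------------------------------------


def _path_fraction_at(f: FlightEvent, times: np.ndarray) -> np.ndarray:
    """Arc-length fraction along a flight's path at given absolute times."""
    m = f.path.shape[0]
    tt = np.linspace(f.t_takeoff, f.t_land, m)
    seg = np.linalg.norm(np.diff(f.path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s /= max(s[-1], 1e-12)
    return np.interp(times, tt, s)


def rate_map_1d(
    flights: list[FlightEvent],
    spikes: SpikeTrain,
    path_cluster_id: int = 0,
    bin_size: float = BIN_SIZE,
    smooth_sigma_bins: float = 1.5,
    fs: float = 100.0,
    min_flights: int = 5,
    min_spike_flights: int = 4,
) -> PathRateMap | None:
    """1D rate map along a repeated path, rescaled take-off -> landing.

    Each flight is mapped onto its arc-length fraction scaled to the mean
    path length; rate = smoothed spike counts / smoothed occupancy with a
    7-sample Gaussian window.  Returns None when the path has fewer than
    ``min_flights`` flights or fewer than ``min_spike_flights`` flights
    carrying spikes (excluded from analysis).
    """
    if len(flights) < min_flights:
        return None
    lengths = [
        float(np.sum(np.linalg.norm(np.diff(f.path, axis=0), axis=1))) for f in flights
    ]
    mean_len = float(np.mean(lengths))
    n_bins = max(2, int(round(mean_len / bin_size)))
    edges = np.linspace(0, mean_len, n_bins + 1)
    occ = np.zeros(n_bins)
    spk = np.zeros(n_bins)
    n_spike_flights = 0
    for f in flights:
        tt = np.arange(f.t_takeoff, f.t_land, 1.0 / fs)
        frac = _path_fraction_at(f, tt)
        occ += np.histogram(frac * mean_len, bins=edges)[0] / fs
        st = spikes.times[(spikes.times >= f.t_takeoff) & (spikes.times <= f.t_land)]
        if st.size:
            n_spike_flights += 1
            sfrac = _path_fraction_at(f, st)
            spk += np.histogram(sfrac * mean_len, bins=edges)[0]
    if n_spike_flights < min_spike_flights:
        return None
    occ_s = gaussian_filter1d(occ, smooth_sigma_bins, mode="constant")
    spk_s = gaussian_filter1d(spk, smooth_sigma_bins, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ_s > 1e-12, spk_s / np.maximum(occ_s, 1e-12), 0.0)
    p = occ_s / occ_s.sum()
    si = si_bits_per_spike(p, rate)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return PathRateMap(path_cluster_id, centres, rate, occ, si,
                       len(flights), n_spike_flights)


def split_half_stability(
    flights: list[FlightEvent],
    spikes: SpikeTrain,
    seed: int | np.random.Generator | None = 0,
    **map_kwargs,
) -> float:
    """Spearman correlation of 1D maps from two random halves of the flights.

    Flights are never split across halves; the split is resampled with the
    given seed.  Returns nan when either half map is excluded.
    """
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(flights))
    half = len(flights) // 2
    kw = dict(map_kwargs)
    kw.setdefault("min_flights", 2)
    kw.setdefault("min_spike_flights", 1)
    m1 = rate_map_1d([flights[i] for i in idx[:half]], spikes, **kw)
    m2 = rate_map_1d([flights[i] for i in idx[half:]], spikes, **kw)
    if m1 is None or m2 is None:
        return np.nan
    n = min(m1.rate.size, m2.rate.size)
    rho, _ = spearmanr(m1.rate[:n], m2.rate[:n])
    return float(rho)


def path_shuffle_test(
    flights: list[FlightEvent],
    spikes: SpikeTrain,
    n_shuffle: int = 1000,
    min_shift: float = 1.0,
    n_paths: int = 1,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = 0,
    **map_kwargs,
) -> ShuffleResult:
    """1D-field significance by circular shuffling within the path's flight
    epochs only, Bonferroni-corrected for the number of paths examined."""
    rng = np.random.default_rng(seed)
    epochs = np.array([[f.t_takeoff, f.t_land] for f in flights])
    emp = rate_map_1d(flights, spikes, **map_kwargs)
    if emp is None:
        return ShuffleResult(np.nan, np.empty(0), False, 1.0)
    ps, span = _to_pseudotime(spikes.times, epochs)
    ms = min(min_shift, span / 4)
    null = np.empty(n_shuffle)
    for k in range(n_shuffle):
        shift = rng.uniform(ms, span - ms)
        shifted = _from_pseudotime(np.sort((ps + shift) % span), epochs)
        m = rate_map_1d(flights, SpikeTrain(shifted), **map_kwargs)
        null[k] = m.si if m is not None else np.nan
    null = null[np.isfinite(null)]
    if not np.isfinite(emp.si) or null.size == 0:
        return ShuffleResult(emp.si, null, False, 1.0)
    thresh = np.quantile(null, 1 - alpha / max(1, n_paths))
    p = (1 + int(np.sum(null >= emp.si))) / (null.size + 1)
    return ShuffleResult(emp.si, null, bool(emp.si > thresh), p)


# ---------------------------------------------------------------------------
# field-parameter recovery
# ---------------------------------------------------------------------------


def fit_gaussian_field(rate_map: RateMap2D, sigma_bins: float = SMOOTH_SIGMA) -> dict:
    """Fit a Gaussian place field plus constant baseline to a 2D rate map.

    The fit forward-models the map construction: the candidate field is
    multiplied by the raw occupancy, convolved with the same Gaussian kernel
    used for the map, and divided by the smoothed occupancy.  The returned
    ``amplitude`` therefore estimates the generative field peak above
    baseline, undistorted by smoothing or occupancy weighting.

    Returns dict(amplitude, centre, sigma, baseline).
    """
    xc = 0.5 * (rate_map.x_edges[:-1] + rate_map.x_edges[1:])
    yc = 0.5 * (rate_map.y_edges[:-1] + rate_map.y_edges[1:])
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    occ = rate_map.occupancy
    occ_s = rate_map.occupancy_smooth
    valid = rate_map.valid
    target = np.nan_to_num(rate_map.rate)[valid]
    # the sampling variance of a rate estimate scales as 1/exposure:
    # weight residuals by sqrt(occupancy) so sparsely visited bins do not
    # dominate the peak estimate
    w = np.sqrt(occ_s[valid])

    def predict(params):
        b, a, x0, y0, s = params
        field = b + a * np.exp(-((gx - x0) ** 2 + (gy - y0) ** 2) / (2 * s**2))
        num = gaussian_filter(field * occ, sigma_bins, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            pred = np.where(occ_s > 1e-12, num / np.maximum(occ_s, 1e-12), 0.0)
        return pred[valid]

    peak = rate_map.peak_location
    r_valid = np.nan_to_num(rate_map.rate)[valid]
    p0 = [max(1e-3, np.median(r_valid)), max(0.1, r_valid.max() - np.median(r_valid)),
          peak[0], peak[1], 0.5]
    res = least_squares(
        lambda p: w * (predict(p) - target), p0,
        bounds=([0, 0, 0, 0, 0.05],
                [np.inf, np.inf, rate_map.x_edges[-1], rate_map.y_edges[-1], 3.0]),
        max_nfev=200,
    )
    b, a, x0, y0, s = res.x
    return dict(amplitude=float(a), centre=np.array([x0, y0]),
                sigma=float(s), baseline=float(b))
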