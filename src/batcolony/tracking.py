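"""Positional preprocessing: smoothing, flight segmentation, rest clustering.

The pipeline mirrors how high-rate indoor tracking of flying bats is cleaned
up in practice: a local quadratic regression everywhere (1 s window), then a
5 s moving median restricted to rest epochs (bats do not crawl between
landings, so rest positions are effectively constant), flight segmentation by
a 0.5 m/s speed threshold, and agglomerative clustering of rest positions
into discrete perch sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import median_filter
from scipy.spatial.distance import pdist

from .synthetic import BatTrack, FlightEvent

__all__ = [
    "RestCluster",
    "smooth_positions",
    "segment_flights",
    "cluster_rest_positions",
    "occupancy_map",
    "exploration_ratio",
    "speed_of",
    "wingbeat_mask",
]

SPEED_THRESHOLD = 0.5  # m/s
MIN_FLIGHT_DURATION = 0.5  # s; suppresses tracking jitter
MERGE_GAP = 0.3  # s; sub-threshold dips shorter than this stay in-flight


@dataclass
class RestCluster:
    """A discrete perch site: centroid, occupancy and member samples."""

    cluster_id: int
    centroid: np.ndarray
    occupancy: float  # seconds
    members: np.ndarray  # sample indices into the rest-sample array


def speed_of(track: BatTrack) -> np.ndarray:
    vel = np.gradient(track.pos, track.t, axis=0)
    return np.linalg.norm(vel, axis=1)


def wingbeat_mask(
    accel_mag: np.ndarray, fs: float, band: tuple[float, float] = (6.0, 10.0),
    threshold: float = 0.3,
) -> np.ndarray:
    """Flight detection from the 8 Hz wingbeat band of the accelerometer.

    Returns True where the rolling RMS of the band-passed magnitude exceeds
    ``threshold`` (m/s^2) -- wingbeats are >1 m/s^2, rest noise is ~0.01.
    """
    sos = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, accel_mag - np.mean(accel_mag))
    win = max(3, int(0.25 * fs))
    power = np.sqrt(
        np.convolve(filt**2, np.ones(win) / win, mode="same")
    )
    return power > threshold


def smooth_positions(
    track: BatTrack,
    regression_window: float = 1.0,
    median_window: float = 5.0,
    max_gap: float = 5.0,
) -> BatTrack:
    """Two-stage position smoothing.

    Stage 1: local quadratic regression (least-squares degree-2 polynomial in
    a centred sliding window, i.e. a Savitzky-Golay filter with uniform
    weights).  Stage 2: a moving median applied only to rest samples (flight
    detection via the wingbeat band of ``accel_mag`` when available,
    otherwise the speed threshold), run separately inside each contiguous
    rest epoch so flight samples never leak into the medians.

    NaN gaps <= 0.5 s are linearly interpolated first; samples inside longer
    gaps are flagged in the returned track's ``valid`` attribute and should
    be excluded downstream.
    """
    fs = track.fs
    pos = track.pos.astype(float).copy()
    valid = ~np.isnan(pos).any(axis=1)
    if not valid.all():
        idx = np.arange(pos.shape[0])
        for d in range(3):
            pos[:, d] = np.interp(idx, idx[valid], pos[valid, d])
    # flag long gaps
    long_gap = np.zeros(pos.shape[0], dtype=bool)
    if not valid.all():
        inv = ~valid
        edges = np.flatnonzero(np.diff(np.r_[False, inv, False]))
        for s, e in zip(edges[::2], edges[1::2]):
            if (e - s) / fs > 0.5:
                long_gap[s:e] = True

    win = int(round(regression_window * fs)) | 1  # odd
    sm = signal.savgol_filter(pos, win, polyorder=2, axis=0, mode="interp")

    if track.accel_mag is not None:
        flight = wingbeat_mask(track.accel_mag, fs)
    else:
        vel = np.gradient(sm, track.t, axis=0)
        flight = np.linalg.norm(vel, axis=1) >= SPEED_THRESHOLD

    mwin = int(round(median_window * fs)) | 1
    out = sm.copy()
    rest = ~flight
    edges = np.flatnonzero(np.diff(np.r_[False, rest, False]))
    for s, e in zip(edges[::2], edges[1::2]):
        seg = sm[s:e]
        w = min(mwin, 2 * seg.shape[0] - 1) | 1
        out[s:e] = median_filter(seg, size=(w, 1), mode="nearest")

    vel = np.gradient(out, track.t, axis=0)
    spd = np.linalg.norm(vel, axis=1)
    heading = np.where(spd >= SPEED_THRESHOLD,
                       np.arctan2(vel[:, 1], vel[:, 0]), np.nan)
    smoothed = BatTrack(track.bat_id, track.t, out, track.accel_mag,
                        heading, flight)
    smoothed.valid = ~long_gap  # type: ignore[attr-defined]
    return smoothed


def segment_flights(
    track: BatTrack,
    speed_threshold: float = SPEED_THRESHOLD,
    min_duration: float = MIN_FLIGHT_DURATION,
    merge_gap: float = MERGE_GAP,
) -> list[FlightEvent]:
    """Flights as maximal supra-threshold speed runs.

    Runs separated by less than ``merge_gap`` are merged, runs shorter than
    ``min_duration`` are dropped; take-off and landing are placed at the
    threshold crossings (first/last supra-threshold sample).
    """
    spd = speed_of(track)
    above = spd >= speed_threshold
    if not above.any():
        return []
    fs = track.fs
    edges = np.flatnonzero(np.diff(np.r_[False, above, False]))
    starts, ends = list(edges[::2]), list(edges[1::2])
    # merge runs separated by short gaps
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if (s - merged[-1][1]) / fs < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    flights = []
    for s, e in merged:
        if (e - s) / fs < min_duration:
            continue
        flights.append(
            FlightEvent(
                track.bat_id,
                track.t[s],
                track.t[e - 1],
                track.pos[s].copy(),
                track.pos[e - 1].copy(),
                track.pos[s:e].copy(),
            )
        )
    return flights


def cluster_rest_positions(
    positions: np.ndarray,
    fs: float = 100.0,
    linkage_cut: float = 0.2,
    min_occupancy: float = 10.0,
    method: str = "single",
    decimate_hz: float = 1.0,
) -> list[RestCluster]:
    """Agglomerative clustering of rest positions into perch sites.

    Clustering runs on a ``decimate_hz`` subsample (rest positions are
    constant over seconds, so this loses nothing and keeps the linkage
    matrix tractable); every rest sample is then assigned to the nearest
    retained centroid.  Clusters occupying less than ``min_occupancy``
    seconds are discarded.  Single linkage by default so contiguous perch
    areas merge; configurable.
    """
    positions = np.asarray(positions, float)
    if positions.shape[0] == 0:
        return []
    step = max(1, int(round(fs / decimate_hz)))
    sub = positions[::step]
    if sub.shape[0] == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(sub), method=method)
        labels = fcluster(z, t=linkage_cut, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        members_sub = np.flatnonzero(labels == lab)
        occ = members_sub.size * step / fs
        if occ < min_occupancy:
            continue
        clusters.append((sub[members_sub].mean(axis=0), occ))
    if not clusters:
        return []
    centroids = np.array([c for c, _ in clusters])
    # assign samples to the nearest retained centroid; samples of discarded
    # (short-occupancy) sites stay unassigned rather than polluting a cluster
    d = np.linalg.norm(positions[:, None, :] - centroids[None], axis=2)
    nearest = np.argmin(d, axis=1)
    within = d[np.arange(d.shape[0]), nearest] <= linkage_cut
    out = []
    for k in range(centroids.shape[0]):
        members = np.flatnonzero((nearest == k) & within)
        if members.size == 0:
            continue
        out.append(
            RestCluster(k, positions[members].mean(axis=0), members.size / fs, members)
        )
    return out


def occupancy_map(
    track: BatTrack,
    bins: int = 21,
    room_xy: tuple[float, float] = (5.6, 5.2),
    rest_only: bool = True,
) -> np.ndarray:
    """2D rest-occupancy (seconds per bin) on a ``bins`` x ``bins`` grid."""
    sel = np.ones(track.t.size, dtype=bool)
    if rest_only and track.flight_mask is not None:
        sel = ~track.flight_mask
    dt = 1.0 / track.fs
    h, _, _ = np.histogram2d(
        track.pos[sel, 0], track.pos[sel, 1],
        bins=bins, range=[[0, room_xy[0]], [0, room_xy[1]]],
    )
    return h * dt


def exploration_ratio(
    track: BatTrack,
    bins: int = 21,
    room_xy: tuple[float, float] = (5.6, 5.2),
    min_occupancy: float = 5.0,
    contour_only: bool = True,
) -> float:
    """Fraction of (contour) bins occupied for at least ``min_occupancy`` s."""
    occ = occupancy_map(track, bins=bins, room_xy=room_xy)
    mask = np.zeros_like(occ, dtype=bool)
    if contour_only:
        mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = True
    else:
        mask[:] = True
    visited = (occ >= min_occupancy) & mask
    return float(visited.sum() / mask.sum())
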