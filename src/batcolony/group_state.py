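"""Group-level structure: configuration state space and social proximity.

A group configuration is the joint vector of all bats' positions while every
bat is at rest.  Configurations are embedded in 2D by Sammon mapping for
visualization, counted combinatorially once positions are discretised to
perch sites, and pairwise social preference is quantified as the excess
fraction of time two bats spend within 0.3 m of each other relative to a
circular-time-shift chance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .synthetic import BatTrack

__all__ = [
    "GroupConfiguration",
    "StateSpaceSummary",
    "ProximityResult",
    "sample_configurations",
    "embed_state_space",
    "sammon",
    "count_states",
    "proximity_index",
]

PROXIMITY_DIST = 0.3  # m


@dataclass(eq=False)
class GroupConfiguration:
    """Joint rest positions of all bats at one sampled instant."""

    t: float
    positions: np.ndarray  # (n_bats, 3)
    site_ids: np.ndarray | None = None  # discrete form (per-bat cluster id)


@dataclass(eq=False)
class StateSpaceSummary:
    n_possible: int
    n_visited: int
    n_frequent: int
    occupancy: dict = field(default_factory=dict)  # state tuple -> seconds
    embedding: np.ndarray | None = None


@dataclass(eq=False)
class ProximityResult:
    pair: tuple[int, int]
    empirical_fraction: float
    proximity_index: float
    p: float
    null: np.ndarray | None = None


def sample_configurations(
    tracks: list[BatTrack], interval: float = 3.0
) -> list[GroupConfiguration]:
    """One configuration per ``interval`` seconds of all-bats-at-rest epochs.

    Within each maximal all-rest epoch [t0, t1) configurations are taken at
    t0, t0+interval, ... (half-open: a grid point falling exactly on the
    epoch end is excluded).
    """
    t = tracks[0].t
    all_rest = np.ones(t.size, dtype=bool)
    for tr in tracks:
        fm = tr.flight_mask
        if fm is None:
            raise ValueError("tracks need flight_mask (run smoothing first)")
        all_rest &= ~fm
    edges = np.flatnonzero(np.diff(np.r_[False, all_rest, False]))
    configs = []
    fs = tracks[0].fs
    for s, e in zip(edges[::2], edges[1::2]):
        t0, t1 = t[s], t[s] + (e - s) / fs
        for tc in np.arange(t0, t1 - 1e-9, interval):
            i = min(int(round((tc - t[0]) * fs)), t.size - 1)
            pos = np.array([tr.pos[i] for tr in tracks])
            configs.append(GroupConfiguration(float(tc), pos))
    return configs


def sammon(
    dist: np.ndarray,
    n_iter: int = 500,
    tol: float = 1e-6,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Sammon nonlinear mapping to 2D from a condensed or square distance matrix.

    Initialized with classical metric scaling; minimised by gradient descent
    with step halving, which makes the stress trace non-increasing by
    construction.  Zero input distances are epsilon-jittered.

    Returns ``(embedding (n, 2), stress_trace)``.
    """
    d = np.asarray(dist, float)
    if d.ndim == 1:
        d = squareform(d)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 configurations")
    off = ~np.eye(n, dtype=bool)
    eps = 1e-6 * (d[off].max() if d[off].max() > 0 else 1.0)
    d = np.where(off & (d < eps), eps, d)

    if init is None:
        # classical metric scaling (Torgerson)
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        vals, vecs = np.linalg.eigh(b)
        order = np.argsort(vals)[::-1][:2]
        y = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
        if y.shape[1] < 2:
            y = np.column_stack([y, np.zeros(n)])
    else:
        y = np.asarray(init, float).copy()

    c = d[off].sum() / 2

    def stress(yy: np.ndarray) -> float:
        dy = squareform(pdist(yy))
        num = ((d - dy) ** 2 / np.where(off, d, 1.0))[off].sum() / 2
        return num / c

    trace = [stress(y)]
    step = 0.3
    for _ in range(n_iter):
        dy = squareform(pdist(y))
        dy_safe = np.where(off, np.maximum(dy, 1e-12), 1.0)
        d_safe = np.where(off, d, 1.0)
        coef = np.where(off, (d - dy_safe) / (d_safe * dy_safe), 0.0)
        diff = y[:, None, :] - y[None, :, :]
        grad = -2.0 / c * np.einsum("ij,ijk->ik", coef, diff)
        # step halving: guarantee monotone decrease
        s = step
        improved = False
        for _ in range(20):
            cand = y - s * grad
            sc = stress(cand)
            if sc <= trace[-1]:
                y = cand
                trace.append(sc)
                improved = True
                break
            s /= 2
        if not improved:
            break
        if len(trace) > 1 and trace[-2] - trace[-1] < tol * max(trace[-2], 1e-30):
            break
    return y, trace


def embed_state_space(
    configs: list[GroupConfiguration], n_iter: int = 500
) -> tuple[np.ndarray, list[float]]:
    """2D Sammon embedding of group configurations (flattened positions)."""
    x = np.array([c.positions.ravel() for c in configs])
    d = squareform(pdist(x))
    return sammon(d, n_iter=n_iter)


def count_states(
    configs: list[GroupConfiguration],
    n_clusters: int,
    interval: float = 3.0,
) -> StateSpaceSummary:
    """Possible / visited / frequent discrete group states.

    ``n_possible = n_clusters ** n_bats``; visited states are the distinct
    observed site-id tuples; frequent states are the visited states whose
    occupancy exceeds the (sample) standard deviation of all visited-state
    occupancies.
    """
    if not configs:
        return StateSpaceSummary(0, 0, 0)
    if configs[0].site_ids is None:
        raise ValueError("configurations need discrete site_ids")
    n_bats = configs[0].site_ids.size
    occ: dict[tuple, float] = {}
    for c in configs:
        key = tuple(int(s) for s in c.site_ids)
        occ[key] = occ.get(key, 0.0) + interval
    values = np.array(list(occ.values()))
    if values.size == 1:
        n_freq = 1
    else:
        n_freq = int(np.sum(values > np.std(values, ddof=1)))
    return StateSpaceSummary(
        n_possible=int(n_clusters**n_bats),
        n_visited=len(occ),
        n_frequent=n_freq,
        occupancy=occ,
    )


def proximity_index(
    track_i: BatTrack | np.ndarray,
    track_j: BatTrack | np.ndarray,
    n_shuffle: int = 1000,
    threshold: float = PROXIMITY_DIST,
    min_shift: float = 60.0,
    fs: float | None = None,
    decimate_hz: float = 10.0,
    seed: int | np.random.Generator | None = 0,
    pair: tuple[int, int] = (0, 1),
) -> ProximityResult:
    """Excess co-location of a bat pair over a circular-shift chance level.

    The empirical value is the fraction of samples with 3D inter-bat
    distance below ``threshold``; chance comes from ``n_shuffle`` circular
    time shifts (uniform, at least ``min_shift`` s away from zero shift) of
    one bat's series.  Position series are decimated to ``decimate_hz``
    first (positions are autocorrelated over seconds, the fraction estimate
    is unchanged).  p uses the (1+#)/(1+n) permutation convention.
    """
    if isinstance(track_i, BatTrack):
        pos_i, pos_j, fs = track_i.pos, track_j.pos, track_i.fs
        pair = (track_i.bat_id, track_j.bat_id)
    else:
        pos_i, pos_j = np.asarray(track_i, float), np.asarray(track_j, float)
        if fs is None:
            raise ValueError("fs required with raw position arrays")
    step = max(1, int(round(fs / decimate_hz)))
    pi, pj = pos_i[::step], pos_j[::step]
    n = min(pi.shape[0], pj.shape[0])
    pi, pj = pi[:n], pj[:n]
    fs_d = fs / step

    emp = float(np.mean(np.linalg.norm(pi - pj, axis=1) < threshold))
    rng = np.random.default_rng(seed)
    min_s = int(round(min_shift * fs_d))
    if 2 * min_s >= n:
        min_s = max(1, n // 4)
    shifts = rng.integers(min_s, n - min_s, size=n_shuffle)
    null = np.empty(n_shuffle)
    for k, s in enumerate(shifts):
        rolled = np.roll(pj, s, axis=0)
        null[k] = np.mean(np.linalg.norm(pi - rolled, axis=1) < threshold)
    p = (1 + int(np.sum(null >= emp))) / (n_shuffle + 1)
    return ProximityResult(pair, emp, emp - float(null.mean()), p, null)
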