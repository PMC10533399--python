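"""Synthetic group-behaviour sessions with known ground truth.

Generates everything the analysis pipeline consumes: per-bat 3D tracks at
100 Hz of bats hopping between clustered rest sites in a flight room,
segmented flights along repeatable paths, accelerometer magnitude with the
8 Hz wingbeat signature, spike trains from the spatial / social / conjunctive
cell model, paired ultrasonic echolocation clicks, and ROI-level calcium
ensembles.  Ground-truth labels (rest sites, per-flight social class,
per-bat landing distances, planted cell parameters, click times) ride along
so downstream recovery can be verified.

The cell model: on 200 ms bins the firing rate is

    lam(t) = lam_spont + lam_spatial(t) + lam_social(t)
    lam_spatial(t) = w(t) * lam_c * exp(-|x(t) - x_c|^2 / (2 sigma_c^2))
    lam_social(t)  = b(t) * lam_s * exp(-(t - t_s)^2 / (2 sigma_s^2))

where w gates firing to flight (decaying within 0.5 s of take-off/landing),
x(t) is the focal bat's 2D position, t_s anchors the social response to
take-off or landing of each flight, and b is true when a conspecific is
within 0.6 m of the landing point (for conjunctive cells additionally only
inside the spatial field).  Spikes are an inhomogeneous Poisson process on
the binned rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "G_ACC",
    "SessionConfig",
    "CellSpec",
    "BatTrack",
    "FlightEvent",
    "SpikeTrain",
    "SyntheticSession",
    "generate_group_session",
    "simulate_cell_rate",
    "sample_spikes",
    "generate_accelerometer",
    "generate_click_audio",
    "generate_roi_ensemble",
    "make_matched_flightset",
]

G_ACC = 9.81  # gravitational acceleration, m s^-2
FS_TRACK = 100.0  # tracking sample rate, Hz
RATE_BIN = 0.2  # cell-model time bin, s
SOCIAL_DIST = 0.6  # conspecific-present threshold at landing, m


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SessionConfig:
    """Parameters of a synthetic group session.

    flight_rate defaults to 77 flights per hour per bat, the observed group
    average; preference_matrix is a symmetric pairwise co-location bias in
    [0, 1] with zero diagonal; social_site_bias gives per-bat site weights.
    """

    n_bats: int = 5
    duration: float = 3600.0
    room: tuple[float, float, float] = (5.6, 5.2, 2.5)
    n_rest_sites: int = 5
    preference_matrix: np.ndarray | None = None
    social_site_bias: np.ndarray | None = None
    flight_rate: float = 77.0
    position_noise: float = 0.005
    grooming_rate: float = 2.0  # bouts per hour per bat
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bats < 2:
            raise ValueError("need at least 2 bats")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if any(r <= 0 for r in self.room):
            raise ValueError("room extents must be positive")
        if self.preference_matrix is None:
            self.preference_matrix = np.zeros((self.n_bats, self.n_bats))
        self.preference_matrix = np.asarray(self.preference_matrix, float)
        p = self.preference_matrix
        if p.shape != (self.n_bats, self.n_bats):
            raise ValueError("preference_matrix must be n_bats x n_bats")
        if not np.allclose(p, p.T) or np.any(np.diag(p) != 0):
            raise ValueError("preference_matrix must be symmetric, zero diagonal")
        if self.social_site_bias is not None:
            self.social_site_bias = np.asarray(self.social_site_bias, float)
            if self.social_site_bias.shape != (self.n_bats, self.n_rest_sites):
                raise ValueError("social_site_bias must be n_bats x n_rest_sites")


@dataclass
class CellSpec:
    """Generative parameters of one simulated hippocampal cell.

    Defaults are the published simulation values: lam_spont = 0.4 Hz,
    lam_c = 8 Hz (spatial peak), lam_s = 4 Hz (social amplitude, signed for
    conjunctive cells where |lam_s| = lam_c), sigma_c = 0.5 m, sigma_s = 0.5 s.
    """

    cell_class: str = "spatial"
    lam_spont: float = 0.4
    lam_c: float = 8.0
    x_c: tuple[float, float] = (2.8, 2.6)
    sigma_c: float = 0.5
    lam_s: float = 0.0
    t_s: str = "landing"
    sigma_s: float = 0.5

    def __post_init__(self) -> None:
        if self.cell_class not in ("spatial", "social", "conjunctive"):
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if self.lam_spont < 0 or self.sigma_c <= 0 or self.sigma_s <= 0:
            raise ValueError("invalid cell parameters")
        if self.t_s not in ("takeoff", "landing"):
            raise ValueError("t_s anchor must be 'takeoff' or 'landing'")
        if self.cell_class == "spatial" and self.lam_s != 0:
            raise ValueError("spatial cells have lam_s = 0")
        if self.cell_class == "social" and self.lam_c != 0:
            raise ValueError("social cells have lam_c = 0")
        if self.cell_class == "conjunctive" and abs(self.lam_s) != self.lam_c:
            raise ValueError("conjunctive cells have |lam_s| = lam_c")


@dataclass(eq=False)
class BatTrack:
    """One bat's position series on the uniform 100 Hz grid."""

    bat_id: int
    t: np.ndarray
    pos: np.ndarray  # (n, 3) metres
    accel_mag: np.ndarray | None = None  # m s^-2
    heading: np.ndarray | None = None  # radians in x-y plane, nan at rest
    flight_mask: np.ndarray | None = None

    @property
    def fs(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    def pos_at(self, times: np.ndarray) -> np.ndarray:
        """Linear interpolation of the 3D position at arbitrary times."""
        times = np.atleast_1d(np.asarray(times, float))
        out = np.empty((times.size, 3))
        for d in range(3):
            out[:, d] = np.interp(times, self.t, self.pos[:, d])
        return out


@dataclass(eq=False)
class FlightEvent:
    """One segmented flight with its end points and path samples."""

    bat_id: int
    t_takeoff: float
    t_land: float
    p_takeoff: np.ndarray
    p_land: np.ndarray
    path: np.ndarray  # (m, 3) position samples takeoff -> landing
    path_cluster: int | None = None

    @property
    def duration(self) -> float:
        return self.t_land - self.t_takeoff

    def __post_init__(self) -> None:
        if self.t_land <= self.t_takeoff:
            raise ValueError("t_land must exceed t_takeoff")


@dataclass(eq=False)
class SpikeTrain:
    """Spike timestamps (seconds from session start) of one unit."""

    times: np.ndarray
    unit_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)

    def __len__(self) -> int:
        return self.times.size

    def count_in(self, t0: float, t1: float) -> int:
        return int(np.searchsorted(self.times, t1) - np.searchsorted(self.times, t0))


@dataclass(eq=False)
class SyntheticSession:
    """A complete generated session plus its ground truth."""

    config: SessionConfig
    tracks: list[BatTrack]
    flights: list[FlightEvent]
    rest_sites: np.ndarray  # (k, 3)
    truth: dict = field(default_factory=dict)

    @property
    def n_bats(self) -> int:
        return len(self.tracks)

    @property
    def duration(self) -> float:
        return self.config.duration

    def flights_of(self, bat_id: int) -> list[FlightEvent]:
        return [f for f in self.flights if f.bat_id == bat_id]


# ---------------------------------------------------------------------------
# behaviour generator
# ---------------------------------------------------------------------------


def _place_rest_sites(rng: np.random.Generator, room, n_sites: int) -> np.ndarray:
    """Rest sites near the upper part of the room, pairwise >= 1.2 m apart."""
    sites = []
    margin = 0.5
    for _ in range(1000):
        cand = np.array(
            [
                rng.uniform(margin, room[0] - margin),
                rng.uniform(margin, room[1] - margin),
                rng.uniform(1.7, room[2] - 0.2),
            ]
        )
        if all(np.linalg.norm(cand[:2] - s[:2]) >= 1.2 for s in sites):
            sites.append(cand)
        if len(sites) == n_sites:
            return np.array(sites)
    raise RuntimeError("could not place rest sites; reduce n_rest_sites")


def _flight_segment(rng, p0, p1, pair_offset, room, v_peak=None):
    """Cubic-spline path p0 -> p1 with a symmetric speed profile.

    The mid-air control point carries a per-site-pair lateral offset and a
    vertical dip so that flights between the same sites follow repeatable
    paths; a small per-flight jitter is added on top.
    """
    chord = p1 - p0
    d = np.linalg.norm(chord)
    mid = 0.5 * (p0 + p1)
    # orthogonal horizontal direction for the lateral bow
    horiz = np.array([-chord[1], chord[0], 0.0])
    nh = np.linalg.norm(horiz)
    if nh > 1e-9:
        horiz /= nh
    ctrl = mid + horiz * (pair_offset[0] + rng.normal(0, 0.05))
    ctrl[2] = max(0.3, mid[2] - (pair_offset[1] + rng.normal(0, 0.05)))
    pts = np.vstack([p0, ctrl, p1])
    spline = CubicSpline([0.0, 0.5, 1.0], pts, axis=0)
    # arc length by fine sampling
    ss = np.linspace(0, 1, 64)
    seg = np.diff(spline(ss), axis=0)
    length = float(np.sum(np.linalg.norm(seg, axis=1)))
    if v_peak is None:
        v_peak = rng.uniform(2.0, 4.0)
    duration = float(np.clip(2.0 * length / v_peak, 1.0, 4.0))
    lo = np.array([0.05, 0.05, 0.05])
    hi = np.asarray(room) - 0.05

    def evaluate(tau: np.ndarray) -> np.ndarray:
        # normalized arc position with speed ~ 1 - cos(2 pi tau), zero at ends
        s = tau - np.sin(2 * np.pi * tau) / (2 * np.pi)
        return np.clip(spline(s), lo, hi)

    return evaluate, duration, d


def generate_group_session(cfg: SessionConfig) -> SyntheticSession:
    """Simulate the group's rest/flight alternation and build 100 Hz tracks.

    Bats rest at one of the clustered sites (position jittered <= 0.1 m,
    fixed per rest epoch) and hop between sites along smooth 1-4 s spline
    flights with peak speed 2-4 m/s.  Landing-site choice is biased by
    ``social_site_bias`` and multiplicatively attracted towards sites
    occupied by preferred partners (``preference_matrix``).  Deterministic
    given ``cfg.seed``.
    """
    seq = np.random.SeedSequence(cfg.seed)
    rng_beh, rng_acc, _rng_aud = [np.random.default_rng(s) for s in seq.spawn(3)]

    n = cfg.n_bats
    sites = _place_rest_sites(rng_beh, cfg.room, cfg.n_rest_sites)
    # per-bat spatial preference: bats favour a couple of self-selected sites
    # (flights concentrate on repeatable paths); drawn once per session unless
    # the config pins explicit biases
    if cfg.social_site_bias is None:
        site_bias = rng_beh.dirichlet(
            np.full(cfg.n_rest_sites, 0.7), size=n
        ) + 0.02
    else:
        site_bias = cfg.social_site_bias
    mean_flight = 2.3
    mean_rest = max(5.0, 3600.0 / cfg.flight_rate - mean_flight - 2.0)

    # per ordered site pair: consistent lateral bow and vertical dip
    pair_offset = {}
    for i in range(cfg.n_rest_sites):
        for j in range(cfg.n_rest_sites):
            if i != j:
                pair_offset[(i, j)] = (rng_beh.normal(0, 0.25), rng_beh.uniform(0.4, 0.9))

    def rest_jitter():
        v = rng_beh.normal(0, 0.03, size=3)
        nv = np.linalg.norm(v)
        if nv > 0.1:
            v *= 0.1 / nv
        return v

    # initial placement by site bias
    site_of = np.empty(n, dtype=int)
    for b in range(n):
        w = site_bias[b].copy()
        site_of[b] = rng_beh.choice(cfg.n_rest_sites, p=w / w.sum())
    segments: list[list] = [[] for _ in range(n)]  # per bat
    rest_pos = [sites[site_of[b]] + rest_jitter() for b in range(n)]
    next_takeoff = np.array(
        [2.0 + rng_beh.exponential(mean_rest) for _ in range(n)]
    )
    rest_start = np.zeros(n)
    flights_raw: list[dict] = []
    eta = 3.0  # strength of the social attraction towards occupied sites

    while True:
        b = int(np.argmin(next_takeoff))
        t0 = next_takeoff[b]
        if t0 >= cfg.duration - 5.0:
            break
        # close the current rest segment
        segments[b].append(("rest", rest_start[b], t0, rest_pos[b].copy()))
        # destination choice
        w = site_bias[b].astype(float).copy()
        w[site_of[b]] = 0.0
        occupancy_pref = np.zeros(cfg.n_rest_sites)
        for o in range(n):
            if o != b:
                occupancy_pref[site_of[o]] += cfg.preference_matrix[b, o]
        w = w * np.exp(eta * occupancy_pref)
        dest = int(rng_beh.choice(cfg.n_rest_sites, p=w / w.sum()))
        p0 = rest_pos[b]
        p1 = sites[dest] + rest_jitter()
        ev, dur, _ = _flight_segment(
            rng_beh, p0, p1, pair_offset[(site_of[b], dest)], cfg.room
        )
        segments[b].append(("flight", t0, t0 + dur, ev))
        flights_raw.append(
            dict(bat=b, t0=t0, t1=t0 + dur, p0=p0.copy(), p1=p1.copy(),
                 ev=ev, pair=(site_of[b], dest))
        )
        site_of[b] = dest
        rest_pos[b] = p1
        rest_start[b] = t0 + dur
        next_takeoff[b] = t0 + dur + 2.0 + rng_beh.exponential(mean_rest)

    for b in range(n):
        segments[b].append(("rest", rest_start[b], cfg.duration, rest_pos[b].copy()))

    # rasterise to the 100 Hz grid
    t_grid = np.arange(0.0, cfg.duration, 1.0 / FS_TRACK)
    m = t_grid.size
    tracks = []
    for b in range(n):
        pos = np.empty((m, 3))
        fmask = np.zeros(m, dtype=bool)
        for kind, ts, te, payload in segments[b]:
            i0 = int(np.ceil(ts * FS_TRACK - 1e-9))
            i1 = min(m, int(np.ceil(te * FS_TRACK - 1e-9)))
            if i1 <= i0:
                continue
            if kind == "rest":
                pos[i0:i1] = payload
            else:
                tau = (t_grid[i0:i1] - ts) / (te - ts)
                pos[i0:i1] = payload(np.clip(tau, 0, 1))
                fmask[i0:i1] = True
        pos = pos + rng_beh.normal(0, cfg.position_noise, size=pos.shape)
        vel = np.gradient(pos, t_grid, axis=0)
        heading = np.where(fmask, np.arctan2(vel[:, 1], vel[:, 0]), np.nan)
        tracks.append(BatTrack(b, t_grid, pos, None, heading, fmask))

    flights = []
    for fr in flights_raw:
        tt = np.arange(
            np.ceil(fr["t0"] * FS_TRACK) / FS_TRACK, fr["t1"], 1.0 / FS_TRACK
        )
        tau = (tt - fr["t0"]) / (fr["t1"] - fr["t0"])
        path = fr["ev"](np.clip(tau, 0, 1))
        path = np.vstack([fr["p0"], path, fr["p1"]])
        flights.append(
            FlightEvent(fr["bat"], fr["t0"], fr["t1"], fr["p0"], fr["p1"], path)
        )
    order = np.argsort([f.t_takeoff for f in flights])
    flights = [flights[i] for i in order]
    site_pairs = [flights_raw[i]["pair"] for i in order]

    session = SyntheticSession(cfg, tracks, flights, sites)
    # ground-truth social labels from positions at landing
    nn_dist = np.empty(len(flights))
    per_bat = np.full((len(flights), n), np.inf)
    for k, f in enumerate(flights):
        others = [o for o in range(n) if o != f.bat_id]
        p_land = f.p_land
        for o in others:
            po = tracks[o].pos_at(f.t_land)[0]
            per_bat[k, o] = np.linalg.norm(po - p_land)
        nn_dist[k] = per_bat[k, others].min()
    labels = np.where(
        nn_dist < SOCIAL_DIST, "social", np.where(nn_dist > 0.9, "non_social", "ambiguous")
    )
    session.truth = dict(
        rest_sites=sites,
        flight_site_pair=site_pairs,
        flight_nn_distance=nn_dist,
        flight_per_bat_distance=per_bat,
        flight_social_label=labels,
    )
    generate_accelerometer(session, rng=rng_acc)
    return session


# ---------------------------------------------------------------------------
# cell model
# ---------------------------------------------------------------------------


def _flight_window_gate(bin_centres: np.ndarray, flights: list[FlightEvent]) -> np.ndarray:
    """w(t): 1 during flight, decaying linearly to 0 within 0.5 s of the
    nearest take-off or landing, 0 elsewhere."""
    w = np.zeros_like(bin_centres)
    if not flights:
        return w
    edges = np.array([[f.t_takeoff, f.t_land] for f in flights])
    starts, ends = edges[:, 0], edges[:, 1]
    idx = np.searchsorted(starts, bin_centres) - 1
    inside = (idx >= 0) & (bin_centres <= ends[np.clip(idx, 0, None)])
    w[inside] = 1.0
    # distance in time to the nearest flight boundary for rest bins
    bounds = np.sort(edges.ravel())
    j = np.searchsorted(bounds, bin_centres)
    d_next = np.where(j < bounds.size, bounds[np.clip(j, 0, bounds.size - 1)] - bin_centres, np.inf)
    d_prev = np.where(j > 0, bin_centres - bounds[np.clip(j - 1, 0, None)], np.inf)
    d = np.minimum(d_next, d_prev)
    ramp = np.clip(1.0 - d / 0.5, 0.0, 1.0)
    return np.where(inside, 1.0, ramp)


def simulate_cell_rate(
    session: SyntheticSession, spec: CellSpec, focal_bat: int
) -> np.ndarray:
    """Firing rate (Hz) of a simulated cell on 200 ms bins.

    Returns an array of length ceil(duration / 0.2); bin i is centred at
    (i + 0.5) * 0.2 s.  The rate is clipped at zero (negative conjunctive
    modulation cannot push a Poisson rate below 0).
    """
    if not 0 <= focal_bat < session.n_bats:
        raise ValueError(f"no bat {focal_bat} in session")
    n_bins = int(np.ceil(session.duration / RATE_BIN))
    centres = (np.arange(n_bins) + 0.5) * RATE_BIN
    track = session.tracks[focal_bat]
    xy = track.pos_at(np.minimum(centres, track.t[-1]))[:, :2]
    flights = session.flights_of(focal_bat)

    lam = np.full(n_bins, spec.lam_spont)
    x_c = np.asarray(spec.x_c, float)
    d2 = np.sum((xy - x_c) ** 2, axis=1)

    if spec.lam_c > 0:
        w = _flight_window_gate(centres, flights)
        lam += w * spec.lam_c * np.exp(-d2 / (2 * spec.sigma_c**2))

    if spec.lam_s != 0:
        nn = session.truth.get("flight_nn_distance")
        idx_of = {id(fl): k for k, fl in enumerate(session.flights)}
        for f in flights:
            if nn is not None:
                b_present = nn[idx_of[id(f)]] < SOCIAL_DIST
            else:
                b_present = _nn_distance_at_landing(session, f) < SOCIAL_DIST
            if not b_present:
                continue
            t_s = f.t_takeoff if spec.t_s == "takeoff" else f.t_land
            sel = np.abs(centres - t_s) < 5 * spec.sigma_s
            bump = spec.lam_s * np.exp(
                -((centres[sel] - t_s) ** 2) / (2 * spec.sigma_s**2)
            )
            if spec.cell_class == "conjunctive":
                bump = np.where(d2[sel] <= spec.sigma_c**2, bump, 0.0)
            lam[sel] += bump
    return np.clip(lam, 0.0, None)


def _nn_distance_at_landing(session: SyntheticSession, f: FlightEvent) -> float:
    d = np.inf
    for o in range(session.n_bats):
        if o == f.bat_id:
            continue
        po = session.tracks[o].pos_at(f.t_land)[0]
        d = min(d, float(np.linalg.norm(po - f.p_land)))
    return d


def sample_spikes(
    rates: np.ndarray,
    seed: int | np.random.Generator | None = 0,
    bin_width: float = RATE_BIN,
    unit_id: int = 0,
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes from a binned rate series.

    Counts per bin are Poisson(rate * bin_width); timestamps are uniform
    within the bin.  Deterministic given the seed.
    """
    rates = np.asarray(rates, float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rates * bin_width)
    times = []
    for i in np.nonzero(counts)[0]:
        times.append(i * bin_width + rng.uniform(0, bin_width, counts[i]))
    if times:
        return SpikeTrain(np.sort(np.concatenate(times)), unit_id)
    return SpikeTrain(np.empty(0), unit_id)


# ---------------------------------------------------------------------------
# accelerometer
# ---------------------------------------------------------------------------


def generate_accelerometer(
    session: SyntheticSession,
    rng: np.random.Generator | None = None,
    wingbeat_hz: float = 8.0,
    wingbeat_amp: float = 2.0,
) -> list[np.ndarray]:
    """Accelerometer magnitude (m s^-2) at 100 Hz for every bat.

    At rest the magnitude stays within 0.03 m s^-2 of g except during
    sparse grooming bouts; during flight an 8 Hz wingbeat oscillation
    dominates.  Results are attached to each track's ``accel_mag``.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(session.config.seed).spawn(3)[1]
        )
    out = []
    groom_rate = session.config.grooming_rate
    for track in session.tracks:
        t = track.t
        mag = G_ACC + rng.uniform(-0.02, 0.02, t.size)
        fm = track.flight_mask
        phase = rng.uniform(0, 2 * np.pi)
        mag[fm] = G_ACC + wingbeat_amp * np.sin(
            2 * np.pi * wingbeat_hz * t[fm] + phase
        ) + rng.normal(0, 0.1, int(fm.sum()))
        # grooming: short high-variance bouts at rest
        n_groom = rng.poisson(groom_rate * session.duration / 3600.0)
        for _ in range(n_groom):
            s = rng.uniform(0, session.duration - 2.0)
            i0, i1 = int(s * FS_TRACK), int((s + rng.uniform(0.5, 2.0)) * FS_TRACK)
            seg = slice(i0, min(i1, t.size))
            if not fm[seg].any():
                mag[seg] = G_ACC + rng.normal(0, 0.15, mag[seg].size)
        track.accel_mag = mag
        out.append(mag)
    return out


# ---------------------------------------------------------------------------
# echolocation audio
# ---------------------------------------------------------------------------


def click_template(fs: float, centre_hz: float = 22500.0, sigma_s: float = 4e-5) -> np.ndarray:
    """Gaussian-windowed tone pip used as the click waveform (unit peak)."""
    half = int(round(4 * sigma_s * fs))
    tt = np.arange(-half, half + 1) / fs
    return np.exp(-(tt**2) / (2 * sigma_s**2)) * np.cos(2 * np.pi * centre_hz * tt)


def generate_click_audio(
    session: SyntheticSession,
    fs: float = 192000.0,
    snr_db: float = 20.0,
    seed: int | np.random.Generator | None = None,
    rest_click_rate: float = 0.0,
    pairs_per_bout: tuple[int, int] = (3, 7),
):
    """Synthetic ultrasonic audio of paired echolocation clicks.

    Clicks come in pairs (intra-pair gap 20 ms; 100 ms from the second click
    of a pair to the first of the next; ~10 % jitter on both), in bouts
    around every flight's take-off and landing.  Background is white noise
    with sd 10^(-snr_db/20) relative to the unit-peak click template.

    Returns ``(waveform float32, truth_click_times)``.
    """
    if fs < 80000:
        raise ValueError("fs must be >= 80 kHz to represent the 10-35 kHz band")
    if seed is None:
        seed = np.random.SeedSequence(session.config.seed).spawn(3)[2]
    rng = np.random.default_rng(seed)
    n_samp = int(session.duration * fs)
    noise_sd = 10 ** (-snr_db / 20.0)
    audio = rng.normal(0, noise_sd, n_samp).astype(np.float32)
    template = click_template(fs).astype(np.float32)
    half = template.size // 2

    anchors = []
    for f in session.flights:
        anchors.extend([f.t_takeoff, f.t_land])
    if rest_click_rate > 0:
        n_extra = rng.poisson(rest_click_rate * session.duration)
        anchors.extend(rng.uniform(0, session.duration, n_extra))

    click_times = []
    for a in sorted(anchors):
        bout_amp = rng.uniform(0.5, 1.5)
        n_pairs = rng.integers(pairs_per_bout[0], pairs_per_bout[1])
        t = a - 0.2 + rng.normal(0, 0.05)
        for _ in range(n_pairs):
            intra = 0.020 * (1 + 0.1 * rng.normal())
            for tc in (t, t + intra):
                if 0.01 < tc < session.duration - 0.01:
                    click_times.append(tc)
                    i = int(round(tc * fs))
                    amp = bout_amp * rng.uniform(0.95, 1.05)
                    lo, hi = i - half, i + half + 1
                    if lo >= 0 and hi <= n_samp:
                        audio[lo:hi] += (amp * template).astype(np.float32)
            t = t + intra + 0.100 * (1 + 0.1 * rng.normal())
    return audio, np.sort(np.array(click_times))


# ---------------------------------------------------------------------------
# ROI ensembles and matched flight sets
# ---------------------------------------------------------------------------


def generate_roi_ensemble(
    n_rois: int = 20,
    n_trials: int = 40,
    modulated_frac: float = 0.5,
    modulation: float = 2.0,
    fov_px: float = 600.0,
    clumped: bool = False,
    seed: int | np.random.Generator | None = 0,
):
    """ROI-level trial activity with planted class-dependent modulation.

    Emulates per-landing window-mean normalized rates of imaged neurons:
    log-normal baseline per ROI, multiplicative gain ``modulation`` on
    social trials for the modulated subset, plus trial noise.  Returns a
    dict with keys ``activity`` (n_trials x n_rois), ``labels`` (bool,
    social), ``centroids`` (n_rois x 2 pixels) and ``modulated`` (bool mask).
    With ``clumped`` the modulated ROIs are placed in one corner of the FOV
    (for the anatomical-clustering test).
    """
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_trials, dtype=bool)
    labels[: n_trials // 2] = True
    rng.shuffle(labels)
    baseline = rng.lognormal(mean=-1.5, sigma=0.4, size=n_rois)
    modulated = np.zeros(n_rois, dtype=bool)
    modulated[: int(round(modulated_frac * n_rois))] = True
    gain = np.where(np.outer(labels, modulated), modulation, 1.0)
    activity = baseline * gain * rng.lognormal(0.0, 0.35, size=(n_trials, n_rois))
    centroids = rng.uniform(0, fov_px, size=(n_rois, 2))
    if clumped:
        k = int(modulated.sum())
        centroids[modulated] = rng.uniform(0, fov_px / 4, size=(k, 2))
    return dict(
        activity=activity, labels=labels, centroids=centroids, modulated=modulated
    )


def make_matched_flightset(
    n_social: int = 20,
    n_nonsocial: int = 20,
    duration_gap: float = 30.0,
    seed: int | np.random.Generator | None = 0,
) -> SyntheticSession:
    """Minimal two-bat session whose focal bat repeats one flight path.

    All flights share take-off and landing sites (kinematics matched up to
    rest jitter); on social flights the second bat sits at the landing site,
    on non-social flights it is far away.  Used for power and calibration
    analyses of the social-modulation machinery with position, heading and
    acceleration held constant by construction.
    """
    rng = np.random.default_rng(seed)
    n_fl = n_social + n_nonsocial
    duration = (n_fl + 1) * duration_gap
    cfg = SessionConfig(n_bats=2, duration=duration, n_rest_sites=2,
                        seed=rng.integers(2**31 - 1))
    site_a = np.array([1.0, 1.0, 2.0])
    site_b = np.array([4.5, 4.0, 2.0])
    far = np.array([4.5, 1.0, 2.0])
    social = np.zeros(n_fl, dtype=bool)
    social[:n_social] = True
    rng.shuffle(social)

    t_grid = np.arange(0.0, duration, 1.0 / FS_TRACK)
    pos0 = np.tile(site_a, (t_grid.size, 1))
    pos1 = np.tile(far, (t_grid.size, 1))
    fmask0 = np.zeros(t_grid.size, dtype=bool)
    flights = []
    pair_offset = (0.3, 0.6)
    for k in range(n_fl):
        t0 = (k + 1) * duration_gap
        p0 = site_a + rng.normal(0, 0.02, 3)
        p1 = site_b + rng.normal(0, 0.02, 3)
        # fixed peak speed: durations identical, kinematics fully matched
        ev, dur, _ = _flight_segment(rng, p0, p1, pair_offset, cfg.room, v_peak=3.0)
        i0 = int(np.ceil(t0 * FS_TRACK))
        i1 = int(np.ceil((t0 + dur) * FS_TRACK))
        tau = (t_grid[i0:i1] - t0) / dur
        pos0[i0:i1] = ev(np.clip(tau, 0, 1))
        fmask0[i0:i1] = True
        # dwell at the landing site for half the gap, then jump back to the
        # take-off site (the jump is far from every analysis window; the
        # return leg itself is irrelevant for window-based analyses)
        pos0[i1:] = site_a
        i_dwell = int(min(t_grid.size, (t0 + dur + duration_gap / 2) * FS_TRACK))
        pos0[i1:i_dwell] = p1
        flights.append(FlightEvent(0, t0, t0 + dur, p0, p1,
                                   np.vstack([p0, ev(np.clip(tau, 0, 1)), p1])))
        # companion bat position during the surrounding epoch
        j0 = int(max(0, (t0 - duration_gap / 2) * FS_TRACK))
        j1 = int(min(t_grid.size, (t0 + dur + duration_gap / 2) * FS_TRACK))
        pos1[j0:j1] = (site_b if social[k] else far) + rng.normal(0, 0.02, 3)
    pos1[: int(duration_gap / 2 * FS_TRACK)] = far
    vel = np.gradient(pos0, t_grid, axis=0)
    heading0 = np.where(fmask0, np.arctan2(vel[:, 1], vel[:, 0]), np.nan)
    tracks = [
        BatTrack(0, t_grid, pos0, None, heading0, fmask0),
        BatTrack(1, t_grid, pos1, None, None, np.zeros(t_grid.size, bool)),
    ]
    sess = SyntheticSession(cfg, tracks, flights, np.vstack([site_a, site_b, far]))
    nn = np.array([
        float(np.linalg.norm(tracks[1].pos_at(f.t_land)[0] - f.p_land))
        for f in flights
    ])
    labels = np.where(nn < SOCIAL_DIST, "social",
                      np.where(nn > 0.9, "non_social", "ambiguous"))
    sess.truth = dict(
        rest_sites=sess.rest_sites,
        flight_nn_distance=nn,
        flight_per_bat_distance=np.column_stack([np.full(n_fl, np.inf), nn]),
        flight_social_label=labels,
        flight_site_pair=[(0, 1)] * n_fl,
        planted_social=social,
    )
    generate_accelerometer(sess, rng=rng)
    return sess
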