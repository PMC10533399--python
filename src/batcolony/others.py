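"""Responses of a stationary bat's cells to other bats' take-offs.

Events are the take-offs of other group members while the recorded bat is
resting with near-zero body acceleration ("behaviourally clamped"); firing
around those events is tested window by window against the per-event mean,
summarized by a response magnitude (projection on a population template) and
by sparseness-style selectivity indexes over take-off positions and flyer
identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import wilcoxon

from .synthetic import G_ACC, BatTrack, FlightEvent, SpikeTrain

__all__ = [
    "TakeoffEvent",
    "PSTH",
    "SelectivityResult",
    "select_low_mobility_takeoffs",
    "takeoff_psth",
    "psth_significance",
    "build_template",
    "response_magnitude",
    "selectivity_index",
    "selectivity_analysis",
]

EVENT_HALF = 1.0  # interval [-1, +1] s around take-off
MOBILITY_THRESH = 0.03  # m s^-2 absolute accelerometer deviation from g
WINDOW = 0.5
STEP = 0.1


@dataclass(eq=False)
class TakeoffEvent:
    flying_bat: int
    t_takeoff: float
    distance: float  # recorded bat to flying bat at take-off, m
    rest_site: int | None = None
    low_mobility: bool = True


@dataclass(eq=False)
class PSTH:
    bin_centres: np.ndarray  # seconds relative to take-off
    raster: np.ndarray  # (n_events, n_bins) rates in Hz
    events: list = field(default_factory=list)

    @property
    def mean_rate(self) -> np.ndarray:
        return self.raster.mean(axis=0)


@dataclass(eq=False)
class SelectivityResult:
    condition: str
    responses: np.ndarray  # r_i per surviving condition value
    condition_values: np.ndarray
    n: int
    si: float
    null: np.ndarray
    significant: bool


def select_low_mobility_takeoffs(
    flights: list[FlightEvent],
    recorded_track: BatTrack,
    recorded_bat: int | None = None,
    half: float = EVENT_HALF,
    mobility_thresh: float = MOBILITY_THRESH,
) -> list[TakeoffEvent]:
    """Non-overlapping take-offs of other bats with the recorded bat still.

    Exclusions: any pair of events whose +/-1 s windows intersect (both
    dropped), windows in which the recorded bat is flying, and windows in
    which its accelerometer magnitude deviates from g by more than 0.03
    m s^-2 at any sample.
    """
    if recorded_bat is None:
        recorded_bat = recorded_track.bat_id
    cand = [f for f in flights if f.bat_id != recorded_bat]
    cand.sort(key=lambda f: f.t_takeoff)
    times = np.array([f.t_takeoff for f in cand])
    keep = np.ones(len(cand), bool)
    for k in range(len(cand) - 1):
        if times[k + 1] - times[k] < 2 * half:
            keep[k] = keep[k + 1] = False
    fs = recorded_track.fs
    t0 = recorded_track.t[0]
    events = []
    for k, f in enumerate(cand):
        if not keep[k]:
            continue
        i0 = int(max(0, (f.t_takeoff - half - t0) * fs))
        i1 = int(min(recorded_track.t.size, (f.t_takeoff + half - t0) * fs))
        if i1 <= i0:
            continue
        if recorded_track.flight_mask is not None and \
                recorded_track.flight_mask[i0:i1].any():
            continue
        if recorded_track.accel_mag is not None:
            dev = np.abs(recorded_track.accel_mag[i0:i1] - G_ACC)
            if np.max(dev) > mobility_thresh:
                continue
        d = float(np.linalg.norm(
            recorded_track.pos_at(f.t_takeoff)[0] - f.p_takeoff
        ))
        events.append(TakeoffEvent(f.bat_id, f.t_takeoff, d))
    return events


def takeoff_psth(
    spikes: SpikeTrain,
    events: list[TakeoffEvent],
    bin_width: float = 0.1,
    half: float = EVENT_HALF,
) -> PSTH:
    """Trial raster of firing rates (Hz) around each take-off."""
    edges = np.arange(-half, half + 1e-9, bin_width)
    centres = 0.5 * (edges[:-1] + edges[1:])
    raster = np.empty((len(events), centres.size))
    for k, ev in enumerate(events):
        rel = spikes.times - ev.t_takeoff
        raster[k] = np.histogram(rel, bins=edges)[0] / bin_width
    return PSTH(centres, raster, list(events))


def psth_significance(
    psth: PSTH,
    window: float = WINDOW,
    step: float = STEP,
    half: float = EVENT_HALF,
    alpha: float = 0.05,
    min_events: int = 20,
    min_rate: float = 0.2,
    session_rate: float | None = None,
) -> dict:
    """Window-wise signed-rank test of event firing against the event mean.

    Sixteen 500 ms windows at 100 ms steps inside [-1, +1] s; per window the
    per-event window rate is compared with the per-event whole-interval mean
    (Wilcoxon signed-rank across events, Bonferroni over windows).  A cell
    is modulated iff any corrected p < alpha; the sign is that of the median
    difference at the most significant window.  Returns
    dict(modulated, sign, p_windows, analysable).
    """
    n_events = psth.raster.shape[0]
    if session_rate is None:
        session_rate = psth.raster.mean()
    if n_events < min_events or session_rate < min_rate:
        return dict(modulated=False, sign=0, p_windows=np.empty(0),
                    analysable=False)
    centres = np.arange(-half + window / 2, half - window / 2 + 1e-9, step)
    whole_mean = psth.raster.mean(axis=1)
    ps = np.ones(centres.size)
    meds = np.zeros(centres.size)
    bc = psth.bin_centres
    for j, c in enumerate(centres):
        sel = (bc >= c - window / 2) & (bc < c + window / 2)
        wrate = psth.raster[:, sel].mean(axis=1)
        diff = wrate - whole_mean
        if np.allclose(diff, 0):
            continue
        try:
            ps[j] = wilcoxon(diff, zero_method="wilcox").pvalue
        except ValueError:
            ps[j] = 1.0
        meds[j] = np.median(diff)
    p_corr = np.minimum(1.0, ps * centres.size)
    modulated = bool(p_corr.min() < alpha)
    sign = int(np.sign(meds[np.argmin(p_corr)])) if modulated else 0
    return dict(modulated=modulated, sign=sign, p_windows=p_corr,
                analysable=True)


def build_template(profiles: np.ndarray) -> np.ndarray:
    """Population template: mean rate profile of all modulated cells,
    rescaled between -1 and 1."""
    mean = np.asarray(profiles, float).mean(axis=0)
    lo, hi = mean.min(), mean.max()
    if hi - lo < 1e-12:
        return np.zeros_like(mean)
    return 2 * (mean - lo) / (hi - lo) - 1


def response_magnitude(profile: np.ndarray, template: np.ndarray) -> float:
    """Scalar projection of a rate profile on the population template
    (mean per-bin product, positive when the shapes agree)."""
    profile = np.asarray(profile, float)
    template = np.asarray(template, float)
    return float(np.dot(profile, template) / profile.size)


def selectivity_index(responses: np.ndarray) -> float:
    """Sparseness-style selectivity over condition responses, in [0, 1].

    SI = (1 - (sum r_i / n)^2 / (sum r_i^2 / n)) / (1 - 1/n); 0 for a
    uniform response vector, 1 for a one-hot response.  Responses must be
    non-negative (callers subtract the minimum first).
    """
    r = np.asarray(responses, float)
    n = r.size
    if n < 2:
        raise ValueError("need at least 2 conditions")
    denom = np.sum(r**2) / n
    if denom <= 0:
        return 0.0
    return float((1 - (np.sum(r) / n) ** 2 / denom) / (1 - 1 / n))


def selectivity_analysis(
    psth: PSTH,
    condition: np.ndarray,
    template: np.ndarray,
    min_repeats: int = 10,
    n_shuffle: int = 100,
    alpha: float = 0.05,
    condition_name: str = "identity",
    seed: int | np.random.Generator | None = 0,
) -> SelectivityResult | None:
    """Selectivity of the take-off response over positions or identities.

    Condition values with fewer than ``min_repeats`` events are discarded;
    the response r_i of each surviving value is the projection of its mean
    rate profile on the template.  Responses are shifted to be non-negative
    (minimum subtracted) before the selectivity formula.  The null permutes
    condition labels across events; significant iff the empirical index
    exceeds the upper 95 % bound of the null.  Returns None when fewer than
    two condition values survive.
    """
    rng = np.random.default_rng(seed)
    condition = np.asarray(condition)
    values, counts = np.unique(condition, return_counts=True)
    values = values[counts >= min_repeats]
    if values.size < 2:
        return None
    keep = np.isin(condition, values)
    raster = psth.raster[keep]
    cond = condition[keep]

    def si_of(labels: np.ndarray) -> float:
        r = np.array([
            response_magnitude(raster[labels == v].mean(axis=0), template)
            for v in values
        ])
        r = r - r.min()
        return selectivity_index(r)

    emp = si_of(cond)
    null = np.array([si_of(rng.permutation(cond)) for _ in range(n_shuffle)])
    thresh = np.quantile(null, 1 - alpha)
    r_emp = np.array([
        response_magnitude(raster[cond == v].mean(axis=0), template)
        for v in values
    ])
    return SelectivityResult(condition_name, r_emp - r_emp.min(), values,
                             values.size, emp, null, bool(emp > thresh))
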