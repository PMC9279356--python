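"""Centre-of-mass collective variables, event detection and conformer clustering.

Baselines for event detection are always computed per-system from the
start of each series (phosphorylation shifts the centre of mass of the
monitored group, so equilibrium distances are not comparable across
systems).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .structure_io import Selection, Trajectory, resolve_selection
from .superpose_rmsd import kabsch_superpose


@dataclass
class CVSeries:
    """Named distance time series between two atom-group centroids."""

    name: str
    times_ns: np.ndarray
    values_A: np.ndarray
    definition: tuple[Selection, Selection] | None = None

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.values_A = np.asarray(self.values_A, dtype=float)
        if self.times_ns.shape != self.values_A.shape:
            raise ValueError("times/values length mismatch")
        if np.any(self.values_A < 0):
            raise ValueError("distances must be >= 0")


@dataclass
class Event:
    type: Literal["ejection", "unbinding"]
    onset_ns: float
    sustained: bool


@dataclass
class EventSet:
    events: list[Event] = field(default_factory=list)

    @property
    def time_to_first_ns(self) -> float | None:
        for e in self.events:
            if e.sustained:
                return e.onset_ns
        return None


@dataclass
class ActivityCall:
    state: Literal["inactive", "partially_active", "active"]
    residue74_bound_start: bool
    residue74_bound_end: bool
    residue74_transition: bool
    site_open: bool
    bound_threshold_A: float
    open_threshold_A: float


def com_distance_series(
    traj: Trajectory,
    selA: Selection | str,
    selB: Selection | str,
    mass_weighted: bool = True,
    window: np.ndarray | None = None,
    name: str = "com_distance",
) -> CVSeries:
    """Euclidean distance between the (mass-weighted) centroids of two groups."""
    selA = selA if isinstance(selA, Selection) else Selection(selA)
    selB = selB if isinstance(selB, Selection) else Selection(selB)
    ia = resolve_selection(traj.topology, selA)
    ib = resolve_selection(traj.topology, selB)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty selection in COM distance")
    if window is None:
        window = np.arange(traj.n_frames)
    window = np.asarray(window, dtype=np.intp)
    masses = traj.topology.masses()
    wa = masses[ia] if mass_weighted else np.ones(ia.size)
    wb = masses[ib] if mass_weighted else np.ones(ib.size)
    values = np.empty(window.size)
    for k, fi in enumerate(window):
        c = traj.frames[fi].coords
        coma = (c[ia] * wa[:, None]).sum(axis=0) / wa.sum()
        comb = (c[ib] * wb[:, None]).sum(axis=0) / wb.sum()
        values[k] = np.linalg.norm(coma - comb)
    return CVSeries(
        name=name,
        times_ns=traj.times_ns[window],
        values_A=values,
        definition=(selA, selB),
    )


def detect_ejection(
    series: CVSeries,
    baseline_window_ns: float,
    delta_A: float = 5.0,
    sustain_ns: float = 5.0,
    event_type: Literal["ejection", "unbinding"] = "ejection",
) -> EventSet:
    """Detect a sustained upward excursion of a COM-distance series.

    The baseline is the series mean over its first ``baseline_window_ns``.
    The onset is the first time the value exceeds baseline + ``delta_A``
    and stays above that level for at least ``sustain_ns``; the event's
    ``sustained`` flag is True only if the series never drops back below
    the level before the end.
    """
    t = series.times_ns
    v = series.values_A
    base_mask = t < t[0] + baseline_window_ns
    if not base_mask.any():
        raise ValueError("empty baseline window")
    level = float(v[base_mask].mean()) + delta_A

    above = v > level
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
    events: list[Event] = []
    i = 0
    n = len(v)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        duration = (j - i) * dt
        if duration >= sustain_ns:
            events.append(
                Event(type=event_type, onset_ns=float(t[i]), sustained=(j == n))
            )
        i = j
    return EventSet(events=events)


def time_to_dissociation(eventset: EventSet) -> float | None:
    """Onset (ns) of the first sustained event; None when there is none.

    A comparative dissociation "rate" between systems is 1/time_to_first.
    """
    return eventset.time_to_first_ns


def dissociation_rate(eventset: EventSet) -> float | None:
    t = eventset.time_to_first_ns
    if t is None or t <= 0:
        return None
    return 1.0 / t


def cdk4_activity_call(
    dist_res74: CVSeries,
    dist_lys_chelix: CVSeries,
    bound_threshold_A: float | None = None,
    open_threshold_A: float | None = None,
    baseline_window_ns: float | None = None,
) -> ActivityCall:
    """Activity state from the inhibitor-anchor and site-openness distances.

    Decision table (total):

    ==============================  ===================  =================
    residue-74 anchor pattern        site openness        state
    ==============================  ===================  =================
    bound throughout                 closed               inactive
    bound throughout                 open                 partially_active
    bound at start, unbound at end   any                  partially_active
    any other mixed pattern          any                  partially_active
    unbound throughout               any                  active
    ==============================  ===================  =================

    Thresholds default to per-series baselines: bound when the anchor
    distance is below baseline mean + 3 A; site open when the Lys/C-helix
    distance exceeds its baseline mean + 2 A, judged over the last quarter
    of the window.
    """
    if len(dist_res74.times_ns) != len(dist_lys_chelix.times_ns) or not np.allclose(
        dist_res74.times_ns, dist_lys_chelix.times_ns
    ):
        raise ValueError("series cover different windows")

    t = dist_res74.times_ns
    span = t[-1] - t[0]
    bw = baseline_window_ns if baseline_window_ns is not None else max(span * 0.1, t[1] - t[0] if len(t) > 1 else span)
    base_mask = t <= t[0] + bw
    if bound_threshold_A is None:
        bound_threshold_A = float(dist_res74.values_A[base_mask].mean()) + 3.0
    if open_threshold_A is None:
        open_threshold_A = float(dist_lys_chelix.values_A[base_mask].mean()) + 2.0

    bound = dist_res74.values_A < bound_threshold_A
    tail = t >= t[-1] - span * 0.25
    site_open = bool(np.mean(dist_lys_chelix.values_A[tail] > open_threshold_A) > 0.5)

    bound_start = bool(bound[base_mask].mean() > 0.5)
    bound_end = bool(bound[tail].mean() > 0.5)
    always_bound = bool(bound.all())
    never_bound = bool(~bound.any())
    transition = bound_start and not bound_end

    if never_bound:
        state = "active"
    elif always_bound:
        state = "inactive" if not site_open else "partially_active"
    else:
        state = "partially_active"
    return ActivityCall(
        state=state,
        residue74_bound_start=bound_start,
        residue74_bound_end=bound_end,
        residue74_transition=transition,
        site_open=site_open,
        bound_threshold_A=float(bound_threshold_A),
        open_threshold_A=float(open_threshold_A),
    )


def cluster_frames(
    traj: Trajectory,
    feature_selection: Selection | str,
    k: int = 2,
    seed: int = 0,
    window: np.ndarray | None = None,
) -> tuple[np.ndarray, list[int]]:
    """k-means over superposed, flattened selection coordinates.

    Every frame's selection is best-fit superposed onto the first analysed
    frame before flattening, so clusters reflect conformation rather than
    rigid-body drift.  Returns (labels, centroid frame indices); the
    centroid of a cluster is the analysed frame closest to its mean.
    Deterministic for a fixed seed.
    """
    from sklearn.cluster import KMeans

    sel = (
        feature_selection
        if isinstance(feature_selection, Selection)
        else Selection(feature_selection)
    )
    idx = resolve_selection(traj.topology, sel)
    if idx.size == 0:
        raise ValueError("empty feature selection")
    if window is None:
        window = np.arange(traj.n_frames)
    window = np.asarray(window, dtype=np.intp)
    if k > window.size:
        raise ValueError(f"k={k} exceeds {window.size} frames")

    ref = traj.frames[window[0]].coords[idx]
    feats = np.empty((window.size, idx.size * 3))
    for row, fi in enumerate(window):
        pts = traj.frames[fi].coords[idx]
        R, tvec, _ = kabsch_superpose(pts, ref)
        feats[row] = (pts @ R.T + tvec).ravel()

    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(feats)
    centroids: list[int] = []
    for c in range(k):
        members = np.nonzero(labels == c)[0]
        d = np.linalg.norm(feats[members] - km.cluster_centers_[c], axis=1)
        centroids.append(int(window[members[int(np.argmin(d))]]))
    return labels, centroids
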