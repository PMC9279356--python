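"""Geometric hydrogen-bond detection and lifetime statistics.

Criteria: donor-acceptor heavy-atom distance <= 3.0 A and D-H...A angle
>= 135 deg, with N/O/F as eligible heavy atoms.  The distance cutoff is
applied between heavy atoms (not H...A), matching common trajectory-
analysis convention.  Contact identity is the (donor, acceptor) heavy-atom
pair; bonds through different hydrogens of one donor are merged.

Lifetime fraction counts every frame the geometric criteria hold.  The
bound/unbound label is a separate rule: a contact is *bound* when at least
one uninterrupted episode lasts 1 ns or longer; shorter episodes are
reported but flagged transient.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Topology, Trajectory
from .structure_io.model import Frame

COVALENT_H_CUTOFF_A = 1.2  # D-H bond inferred below this distance


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance_A: float = 3.0
    min_dha_angle_deg: float = 135.0
    heavy_elements: frozenset = frozenset({"N", "O", "F"})

    def __post_init__(self) -> None:
        if self.max_da_distance_A <= 0:
            raise ValueError("distance cutoff must be > 0")
        if not 0 < self.min_dha_angle_deg <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass
class ContactTimeSeries:
    """Per-frame presence mask for one donor-acceptor contact."""

    donor: int
    acceptor: int
    mask: np.ndarray
    frame_interval_ns: float
    times_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class PersistenceRecord:
    """Lifetime summary of one contact with its bound/unbound label."""

    donor: int
    acceptor: int
    chain_pair: tuple[str, str]
    intermolecular: bool
    lifetime_fraction: float
    bound_episodes: list[tuple[float, float]]  # (start_ns, end_ns), all episodes
    transient_flags: list[bool]  # parallel to bound_episodes
    is_bound: bool


def _heavy_indices(topology: Topology, criteria: HBondCriteria) -> np.ndarray:
    return np.array(
        [i for i, a in enumerate(topology.atoms) if a.element in criteria.heavy_elements],
        dtype=np.intp,
    )


def find_donor_hydrogens(
    frame: Frame, topology: Topology, criteria: HBondCriteria
) -> dict[int, list[int]]:
    """Map eligible heavy atoms to covalently bonded hydrogens (d < 1.2 A)."""
    h_idx = np.array(
        [i for i, a in enumerate(topology.atoms) if a.element == "H"], dtype=np.intp
    )
    heavy = _heavy_indices(topology, criteria)
    donors: dict[int, list[int]] = {int(i): [] for i in heavy}
    if h_idx.size == 0 or heavy.size == 0:
        return donors
    tree = cKDTree(frame.coords[heavy])
    for h in h_idx:
        for local in tree.query_ball_point(frame.coords[h], COVALENT_H_CUTOFF_A):
            donors[int(heavy[local])].append(int(h))
    return donors


def detect_frame_hbonds(
    frame: Frame,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
) -> set[tuple[int, int | None, int]]:
    """Hydrogen bonds in one frame as (donor, hydrogen|None, acceptor) triples.

    Donors are N/O/F heavy atoms carrying at least one hydrogen; when the
    topology has no hydrogens at all the detection falls back to a
    distance-only criterion and reports ``hydrogen=None`` (no-H mode).
    """
    heavy = _heavy_indices(topology, criteria)
    if heavy.size < 2:
        return set()
    donor_h = find_donor_hydrogens(frame, topology, criteria)
    no_h_mode = all(len(v) == 0 for v in donor_h.values())

    coords = frame.coords
    tree = cKDTree(coords[heavy])
    pairs = tree.query_pairs(criteria.max_da_distance_A)
    result: set[tuple[int, int | None, int]] = set()
    min_cos = np.cos(np.deg2rad(criteria.min_dha_angle_deg))
    for a_loc, b_loc in pairs:
        i, j = int(heavy[a_loc]), int(heavy[b_loc])
        ai, aj = topology.atoms[i], topology.atoms[j]
        if ai.residue_key() == aj.residue_key():
            continue
        for donor, acceptor in ((i, j), (j, i)):
            if no_h_mode:
                result.add((donor, None, acceptor))
                continue
            hydrogens = donor_h.get(donor, [])
            if not hydrogens:
                continue
            best_h, best_cos = None, 2.0
            for h in hydrogens:
                # D-H-A angle via vectors H->D and H->A
                v1 = coords[donor] - coords[h]
                v2 = coords[acceptor] - coords[h]
                c = float(
                    np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                )
                if c < best_cos:
                    best_cos, best_h = c, h
            # angle >= cutoff  <=>  cos(angle) <= cos(cutoff)
            if best_h is not None and best_cos <= min_cos + 1e-12:
                result.add((donor, best_h, acceptor))
    return result


def _pair_present(
    frame: Frame,
    topology: Topology,
    donor: int,
    acceptor: int,
    criteria: HBondCriteria,
) -> bool:
    coords = frame.coords
    d = float(np.linalg.norm(coords[acceptor] - coords[donor]))
    if d > criteria.max_da_distance_A:
        return False
    donor_h = find_donor_hydrogens(frame, topology, criteria)
    hydrogens = donor_h.get(donor, [])
    if not any(len(v) for v in donor_h.values()):
        return True  # no-H mode: distance only
    if not hydrogens:
        return False
    min_cos = np.cos(np.deg2rad(criteria.min_dha_angle_deg))
    for h in hydrogens:
        v1 = coords[donor] - coords[h]
        v2 = coords[acceptor] - coords[h]
        c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        if c <= min_cos + 1e-12:
            return True
    return False


def contact_series(
    traj: Trajectory,
    pair: tuple[int, int],
    criteria: HBondCriteria = HBondCriteria(),
    window: np.ndarray | None = None,
) -> ContactTimeSeries:
    """Presence mask of one (donor, acceptor) pair over the analysis window.

    ``window`` is an array of frame indices (e.g. from
    :func:`~trimd.superpose_rmsd.trim_frames`); None means all frames.
    """
    donor, acceptor = pair
    if window is None:
        window = np.arange(traj.n_frames)
    window = np.asarray(window, dtype=np.intp)
    if window.size == 0:
        raise ValueError("empty analysis window")
    mask = np.zeros(window.size, dtype=bool)
    for k, fi in enumerate(window):
        mask[k] = _pair_present(traj.frames[fi], traj.topology, donor, acceptor, criteria)
    times = traj.times_ns[window]
    return ContactTimeSeries(
        donor=donor,
        acceptor=acceptor,
        mask=mask,
        frame_interval_ns=traj.frame_interval_ns,
        times_ns=times,
    )


def lifetime_fraction(series: ContactTimeSeries) -> float:
    """Fraction of analysed frames in which the contact is present."""
    if series.mask.size == 0:
        raise ValueError("empty mask")
    return float(series.mask.sum() / series.mask.size)


def _episodes(mask: np.ndarray, interval: float) -> list[tuple[int, int]]:
    """Maximal runs of True as (start_index, stop_index_exclusive)."""
    runs = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(mask)))
    return runs


def classify_bound(
    series: ContactTimeSeries, min_episode_ns: float = 1.0, topology: Topology | None = None
) -> PersistenceRecord:
    """Label a contact bound/unbound by its longest uninterrupted episode.

    An episode of n consecutive present frames lasts ``n * frame_interval``;
    the contact is bound when any episode reaches ``min_episode_ns`` (1 ns
    by default).  Sub-threshold episodes are kept and flagged transient.
    """
    dt = series.frame_interval_ns
    t0 = float(series.times_ns[0]) if series.times_ns is not None else 0.0
    episodes: list[tuple[float, float]] = []
    transient: list[bool] = []
    is_bound = False
    for start, stop in _episodes(series.mask, dt):
        dur = (stop - start) * dt
        episodes.append((t0 + start * dt, t0 + stop * dt))
        short = dur < min_episode_ns
        transient.append(short)
        if not short:
            is_bound = True
    chain_pair = ("?", "?")
    inter = False
    if topology is not None:
        cd = topology.atoms[series.donor].chain_id
        ca = topology.atoms[series.acceptor].chain_id
        chain_pair = tuple(sorted((cd, ca)))
        inter = cd != ca
    return PersistenceRecord(
        donor=series.donor,
        acceptor=series.acceptor,
        chain_pair=chain_pair,
        intermolecular=inter,
        lifetime_fraction=lifetime_fraction(series),
        bound_episodes=episodes,
        transient_flags=transient,
        is_bound=is_bound,
    )


def persistent_network(
    traj: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
    threshold: float = 0.5,
    chain_pairs: set[tuple[str, str]] | None = None,
    window: np.ndarray | None = None,
    min_episode_ns: float = 1.0,
) -> list[PersistenceRecord]:
    """Contacts with lifetime fraction above ``threshold``, sorted descending.

    ``chain_pairs`` restricts to intermolecular pairs of interest (e.g.
    {('A','B'), ('A','C'), ('B','C')}); None keeps every intermolecular
    pair.  Detection runs framewise over the window; per-pair masks are
    accumulated, then filtered at the threshold.
    """
    if window is None:
        window = np.arange(traj.n_frames)
    window = np.asarray(window, dtype=np.intp)
    if window.size == 0:
        raise ValueError("empty analysis window")
    norm_pairs = (
        {tuple(sorted(p)) for p in chain_pairs} if chain_pairs is not None else None
    )

    top = traj.topology
    masks: dict[tuple[int, int], np.ndarray] = {}
    for k, fi in enumerate(window):
        for donor, _h, acceptor in detect_frame_hbonds(traj.frames[fi], top, criteria):
            cd, ca = top.atoms[donor].chain_id, top.atoms[acceptor].chain_id
            if cd == ca:
                continue
            if norm_pairs is not None and tuple(sorted((cd, ca))) not in norm_pairs:
                continue
            key = (donor, acceptor)
            if key not in masks:
                masks[key] = np.zeros(window.size, dtype=bool)
            masks[key][k] = True

    records = []
    times = traj.times_ns[window]
    for (donor, acceptor), mask in masks.items():
        series = ContactTimeSeries(
            donor=donor,
            acceptor=acceptor,
            mask=mask,
            frame_interval_ns=traj.frame_interval_ns,
            times_ns=times,
        )
        rec = classify_bound(series, min_episode_ns=min_episode_ns, topology=top)
        if rec.lifetime_fraction > threshold:
            records.append(rec)
    records.sort(key=lambda r: (-r.lifetime_fraction, r.donor, r.acceptor))
    return records


def network_table(records: list[PersistenceRecord], topology: Topology):
    """Persistence records as a pandas DataFrame (the report TSV schema)."""
    import pandas as pd

    rows = []
    for r in records:
        d, a = topology.atoms[r.donor], topology.atoms[r.acceptor]
        longest = max(
            (e[1] - e[0] for e in r.bound_episodes), default=0.0
        )
        rows.append(
            {
                "donor_chain": d.chain_id,
                "donor_resid": d.residue_seq,
                "donor_resname": d.residue_name,
                "donor_atom": d.name,
                "acceptor_chain": a.chain_id,
                "acceptor_resid": a.residue_seq,
                "acceptor_resname": a.residue_name,
                "acceptor_atom": a.name,
                "lifetime_fraction": r.lifetime_fraction,
                "n_episodes": len(r.bound_episodes),
                "longest_episode_ns": longest,
                "is_bound": int(r.is_bound),
            }
        )
    return pd.DataFrame(rows)
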