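"""Solvent-accessible surface area by linear combinations of pairwise overlaps.

Per heavy atom i with solvent-expanded radius R_i = r_i + probe:

    A_i = P1*S_i + P2*sum_j A_ij + P3*sum_{j,k in N(i), k in N(j)} A_jk
          + P4*sum_j [ A_ij * sum_{k in N(i) inters N(j)} A_jk ]

where S_i = 4 pi R_i^2, N(i) are the spheres overlapping sphere i, and
A_ij is the area of the spherical cap of sphere i buried inside sphere j.
Hydrogens are excluded (united-atom treatment) and values are clamped at
zero.

Atom classes are keyed by (element, heavy-neighbour count); the shipped
table carries published-style coefficients for common protein classes and
a first-order generic row (P1=1, P2=-1, P3=P4=0) used, with a warning, for
anything unmatched — exact for isolated atoms and pairwise-only overlaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Topology, Trajectory
from .structure_io.model import Frame

logger = logging.getLogger(__name__)

PROBE_RADIUS_A = 1.4
COVALENT_CUTOFF_A = 1.9  # heavy-atom bond inference for class assignment

#: fallback van der Waals radii by element (A)
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "F": 1.47}
GENERIC_RADIUS = 1.70

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "HN"}


@dataclass(frozen=True)
class LCPOClass:
    radius: float
    p1: float
    p2: float
    p3: float
    p4: float


#: generic heavy-atom row: P1 = 1 keeps the isolated-sphere limit exact;
#: P2..P4 were least-squares fitted against a point-sampling oracle on
#: random overlapping sphere clusters (radius 1.7 + 1.4 A probe).
GENERIC_LCPO = LCPOClass(GENERIC_RADIUS, 1.0, -1.0008943, -0.043988860, 0.0082849883)


@dataclass
class LCPOParams:
    """Coefficient table keyed by (element, n_heavy_neighbours)."""

    classes: dict[tuple[str, int], LCPOClass] = field(default_factory=dict)
    generic: LCPOClass = GENERIC_LCPO
    probe_radius: float = PROBE_RADIUS_A

    def lookup(self, element: str, n_neighbors: int) -> LCPOClass:
        cls = self.classes.get((element, n_neighbors))
        if cls is None:
            cls = self.classes.get((element, -1))  # element-wide row
        if cls is None:
            r = DEFAULT_RADII.get(element, GENERIC_RADIUS)
            cls = LCPOClass(r, self.generic.p1, self.generic.p2, self.generic.p3, self.generic.p4)
        return cls


def load_default_params() -> LCPOParams:
    """Coefficient table shipped with the package (data/lcpo_params.tsv)."""
    path = resources.files("trimd.data").joinpath("lcpo_params.tsv")
    df = pd.read_csv(str(path), sep="\t", comment="#")
    classes = {}
    for _, row in df.iterrows():
        key = (str(row["element"]), int(row["n_bonds"]))
        classes[key] = LCPOClass(
            float(row["radius"]), float(row["p1"]), float(row["p2"]),
            float(row["p3"]), float(row["p4"]),
        )
    return LCPOParams(classes=classes)


def _pair_overlap_area(Ri: float, Rj: float, d: float) -> float:
    """Area of sphere i's cap buried inside sphere j (0 if disjoint)."""
    if d >= Ri + Rj:
        return 0.0
    if d + Ri <= Rj:
        return 4.0 * np.pi * Ri * Ri  # sphere i fully inside j
    if d + Rj <= Ri:
        return 0.0  # j inside i: no cap of i buried
    return 2.0 * np.pi * Ri * (Ri - d / 2.0 - (Ri * Ri - Rj * Rj) / (2.0 * d))


def lcpo_atom_sasa(
    frame: Frame,
    topology: Topology,
    params: LCPOParams | None = None,
    warn_fallback: bool = True,
) -> np.ndarray:
    """Per-atom SASA (A^2); hydrogens get exactly 0."""
    if params is None:
        params = load_default_params()
    coords = frame.coords
    heavy = np.array(
        [i for i, a in enumerate(topology.atoms) if a.element != "H"], dtype=np.intp
    )
    out = np.zeros(topology.n_atoms)
    if heavy.size == 0:
        return out

    hcoords = coords[heavy]
    # heavy-neighbour counts for class assignment (covalent distance)
    bond_tree = cKDTree(hcoords)
    bond_counts = np.array(
        [len(bond_tree.query_ball_point(hcoords[k], COVALENT_CUTOFF_A)) - 1
         for k in range(heavy.size)]
    )

    radii = np.empty(heavy.size)
    coeffs = []
    missing = 0
    for k, gi in enumerate(heavy):
        atom = topology.atoms[gi]
        cls = params.lookup(atom.element, int(bond_counts[k]))
        if (atom.element, int(bond_counts[k])) not in params.classes and (
            atom.element, -1) not in params.classes:
            missing += 1
        r = atom.radius if atom.radius is not None else cls.radius
        radii[k] = r + params.probe_radius
        coeffs.append(cls)
    if missing and warn_fallback:
        logger.warning("LCPO: %d atoms fell back to the generic parameter row", missing)

    rmax = radii.max()
    tree = cKDTree(hcoords)
    neighbor_lists = tree.query_ball_tree(tree, 2.0 * rmax)

    # true overlap neighbours and pairwise buried-cap areas
    neighbors: list[list[int]] = [[] for _ in range(heavy.size)]
    area: dict[tuple[int, int], float] = {}
    for k in range(heavy.size):
        for m in neighbor_lists[k]:
            if m == k:
                continue
            d = float(np.linalg.norm(hcoords[k] - hcoords[m]))
            if d < radii[k] + radii[m]:
                neighbors[k].append(m)
                area[(k, m)] = _pair_overlap_area(radii[k], radii[m], d)

    for k in range(heavy.size):
        cls = coeffs[k]
        S = 4.0 * np.pi * radii[k] ** 2
        nb = neighbors[k]
        sum_aij = sum(area[(k, j)] for j in nb)
        sum_ajk = 0.0
        sum_cross = 0.0
        nbset = set(nb)
        for j in nb:
            inner = 0.0
            for m in neighbors[j]:
                if m != k and m in nbset:
                    inner += area[(j, m)]
            sum_ajk += inner
            sum_cross += area[(k, j)] * inner
        # the P3/P4 terms are perturbative corrections for moderate overlap;
        # when pairwise subtraction alone buries the sphere they extrapolate
        # badly, so a fully covered atom is reported as 0 directly
        base = cls.p1 * S + cls.p2 * sum_aij
        if base <= 0.0:
            out[heavy[k]] = 0.0
        else:
            val = base + cls.p3 * sum_ajk + cls.p4 * sum_cross
            out[heavy[k]] = min(max(val, 0.0), cls.p1 * S)
    return out


@dataclass
class SASASeries:
    """Per-frame SASA (A^2) of one target residue."""

    chain_id: str
    residue_seq: int
    times_ns: np.ndarray
    values_A2: np.ndarray
    side_chain_only: bool = True
    accessibility_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values_A2 = np.asarray(self.values_A2, dtype=float)
        if np.any(self.values_A2 < 0):
            raise ValueError("negative SASA")


def residue_sasa_series(
    traj: Trajectory,
    residue: tuple[str, int],
    params: LCPOParams | None = None,
    window: np.ndarray | None = None,
    side_chain_only: bool = True,
) -> SASASeries:
    """SASA of one residue per frame, computed in the full-system context.

    ``side_chain_only`` (default) sums heavy side-chain atoms; set False
    for the whole residue.
    """
    chain_id, resseq = residue
    atom_idx = traj.topology.atom_indices_of_residue(chain_id, resseq)
    if atom_idx.size == 0:
        raise ValueError(f"unknown residue {chain_id}/{resseq}")
    if params is None:
        params = load_default_params()
    if window is None:
        window = np.arange(traj.n_frames)
    window = np.asarray(window, dtype=np.intp)

    keep = []
    for i in atom_idx:
        a = traj.topology.atoms[i]
        if a.element == "H":
            continue
        if side_chain_only and a.name in BACKBONE_NAMES:
            continue
        keep.append(i)
    if not keep:
        keep = [i for i in atom_idx if traj.topology.atoms[i].element != "H"]

    values = np.empty(window.size)
    for k, fi in enumerate(window):
        per_atom = lcpo_atom_sasa(
            traj.frames[fi], traj.topology, params, warn_fallback=(k == 0)
        )
        values[k] = per_atom[keep].sum()
    return SASASeries(
        chain_id=chain_id,
        residue_seq=resseq,
        times_ns=traj.times_ns[window],
        values_A2=values,
        side_chain_only=side_chain_only,
    )


@dataclass
class AccessibilitySummary:
    fraction_accessible: float
    n_switches: int
    label: str  # 'buried' | 'exposed' | 'switching'


def classify_accessibility(
    series: SASASeries, threshold_A2: float = 10.0
) -> tuple[np.ndarray, AccessibilitySummary]:
    """Threshold a SASA series into accessible/inaccessible states."""
    if threshold_A2 < 0:
        raise ValueError("threshold must be >= 0")
    mask = series.values_A2 > threshold_A2
    series.accessibility_mask = mask
    frac = float(mask.mean()) if mask.size else 0.0
    switches = int(np.count_nonzero(np.diff(mask.astype(int))))
    if frac == 0.0:
        label = "buried"
    elif frac == 1.0:
        label = "exposed"
    else:
        label = "switching"
    return mask, AccessibilitySummary(frac, switches, label)


@dataclass
class SASADensity:
    grid_A2: np.ndarray
    density: np.ndarray
    bandwidth: float
    degenerate: bool


def sasa_density(
    series_set: list[SASASeries], grid_points: int = 512
) -> SASADensity:
    """Gaussian KDE (Silverman bandwidth) of pooled SASA samples.

    Pools every series (e.g. replicate simulations); an all-equal sample
    cannot support a KDE and is returned as a flagged delta-like density.
    """
    sample = np.concatenate([s.values_A2 for s in series_set])
    if sample.size < 10:
        raise ValueError("pooled sample must have >= 10 points")
    std = sample.std(ddof=1)
    if std == 0.0:
        grid = np.array([sample[0]])
        return SASADensity(grid, np.array([np.inf]), 0.0, degenerate=True)
    from scipy.stats import gaussian_kde

    kde = gaussian_kde(sample, bw_method="silverman")
    bw = float(kde.factor * std)
    lo = max(0.0, sample.min() - 3 * bw)
    hi = sample.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_points)
    dens = kde(grid)
    return SASADensity(grid, dens, bw, degenerate=False)
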