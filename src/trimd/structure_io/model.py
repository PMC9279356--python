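"""Topology and trajectory data model.

Coordinates live in :class:`Frame` arrays; :class:`Atom` records are
coordinate-free descriptors shared by every frame of a trajectory.
Residue numbering is 1-based author numbering as found in the input file;
nothing is renumbered on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

# Periodic-table symbols accepted for Atom.element (one- and two-letter).
ELEMENTS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U""".split()
)

#: Standard atomic masses (amu) for the elements this toolkit routinely sees.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
    "MG": 24.305, "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078,
}


@dataclass
class Atom:
    """One atom descriptor; coordinates are stored per-frame, not here.

    ``charge`` (e), ``lj_sigma``/``lj_epsilon`` (A, kcal/mol) and ``radius``
    (A) are optional per-atom parameters filled in by
    :func:`~trimd.structure_io.params.attach_parameters`.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    charge: Optional[float] = None
    lj_sigma: Optional[float] = None
    lj_epsilon: Optional[float] = None
    radius: Optional[float] = None

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown element symbol {self.element!r}")

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element.upper(), 12.011)

    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_seq)


class Topology:
    """Ordered atom list plus derived chain/residue indexing.

    Invariants: every atom maps to exactly one residue; residues are listed
    in file order (sorted by residue_seq within each chain on well-formed
    input).
    """

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: list[Atom] = list(atoms)
        self._residues: list[tuple[str, int, str]] = []
        self._residue_of_atom = np.empty(len(self.atoms), dtype=np.intp)
        seen: dict[tuple[str, int], int] = {}
        for i, a in enumerate(self.atoms):
            key = a.residue_key()
            if key not in seen:
                seen[key] = len(self._residues)
                self._residues.append((a.chain_id, a.residue_seq, a.residue_name))
            self._residue_of_atom[i] = seen[key]
        self._chains: list[str] = []
        for a in self.atoms:
            if a.chain_id not in self._chains:
                self._chains.append(a.chain_id)

    # -- basic views -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        return list(self._chains)

    @property
    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered (chain_id, residue_seq, residue_name) triples."""
        return list(self._residues)

    @property
    def n_residues(self) -> int:
        return len(self._residues)

    def residue_index_of_atom(self, atom_index: int) -> int:
        return int(self._residue_of_atom[atom_index])

    def atom_indices_of_residue(self, chain_id: str, residue_seq: int) -> np.ndarray:
        """Sorted atom indices of one residue; empty array if absent."""
        hits = [
            i
            for i, a in enumerate(self.atoms)
            if a.chain_id == chain_id and a.residue_seq == residue_seq
        ]
        return np.asarray(hits, dtype=np.intp)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def with_atoms(self, atoms: Sequence[Atom]) -> "Topology":
        return Topology(atoms)

    def copy(self) -> "Topology":
        return Topology([replace(a) for a in self.atoms])

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)


@dataclass
class Frame:
    """One coordinate set (N x 3, Angstrom) at a trajectory time (ns)."""

    coords: np.ndarray
    time_ns: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an N x 3 array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.time_ns < 0:
            raise ValueError("time_ns must be >= 0")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """A topology plus ordered frames with a uniform frame -> ns mapping."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)
    frame_interval_ns: float = 0.1

    def __post_init__(self) -> None:
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be > 0")
        n = self.topology.n_atoms
        for k, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {k} has {f.n_atoms} atoms, topology has {n}"
                )
        times = self.times_ns
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def times_ns(self) -> np.ndarray:
        return np.array([f.time_ns for f in self.frames], dtype=float)

    def coords_array(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_atoms, 3)."""
        return np.stack([f.coords for f in self.frames], axis=0)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)
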