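"""Secondary-structure assignment (DSSP-style) and trajectory SS fractions.

Backbone H-bonds are scored with the Kabsch-Sander electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

and assigned when E < -0.5 kcal/mol.  n-turns (n = 3, 4, 5) come from
CO(i)...HN(i+n) bonds; two consecutive n-turns start a helix (G/H/I),
bridges build B/E, leftover turns give T, high C-alpha curvature gives S,
everything else C.  Code priority when several patterns apply:
H > E > G > I > B > T > S > C.

Amide hydrogens are reconstructed when absent: H sits 1.0 A from N along
the unit vector from the previous residue's O to its C.  Proline never
donates.  Chains are split at C-alpha breaks (> 4.5 A) and at chain-id
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Topology, Trajectory
from .structure_io.model import Frame

KS_Q1Q2_FACTOR = 0.084 * 332.0  # kcal/mol * A
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
CA_BREAK_CUTOFF = 4.5  # A
BEND_ANGLE_DEG = 70.0
MIN_COINCIDENT = 1e-6

SS_CODES = ("H", "G", "I", "E", "B", "T", "S", "C")


def ks_hbond_energy(
    c_pos: np.ndarray, o_pos: np.ndarray, n_pos: np.ndarray, h_pos: np.ndarray
) -> float:
    """Kabsch-Sander backbone H-bond energy for acceptor C=O, donor N-H."""
    c_pos, o_pos, n_pos, h_pos = (
        np.asarray(p, dtype=float) for p in (c_pos, o_pos, n_pos, h_pos)
    )
    r_on = np.linalg.norm(o_pos - n_pos)
    r_ch = np.linalg.norm(c_pos - h_pos)
    r_oh = np.linalg.norm(o_pos - h_pos)
    r_cn = np.linalg.norm(c_pos - n_pos)
    if min(r_on, r_ch, r_oh, r_cn) < MIN_COINCIDENT:
        raise ValueError("coincident atoms in H-bond energy evaluation")
    return float(KS_Q1Q2_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


@dataclass
class SSAssignment:
    """Per-residue DSSP codes for one frame."""

    codes: list[str]  # one of SS_CODES per residue, topology residue order
    residues: list[tuple[str, int, str]]
    hbond_energies: dict[tuple[int, int], float]  # (acceptor_res, donor_res) -> E

    def as_string(self) -> str:
        return "".join(self.codes)


class _BackboneView:
    """Backbone atom positions per residue, with reconstructed amide H."""

    def __init__(self, frame: Frame, topology: Topology):
        nres = topology.n_residues
        self.n = np.full((nres, 3), np.nan)
        self.ca = np.full((nres, 3), np.nan)
        self.c = np.full((nres, 3), np.nan)
        self.o = np.full((nres, 3), np.nan)
        self.h = np.full((nres, 3), np.nan)
        self.has_h = np.zeros(nres, dtype=bool)
        self.resnames = [r[2] for r in topology.residues]
        self.chain_of = [r[0] for r in topology.residues]
        for i, atom in enumerate(topology.atoms):
            ri = topology.residue_index_of_atom(i)
            xyz = frame.coords[i]
            if atom.name == "N":
                self.n[ri] = xyz
            elif atom.name == "CA":
                self.ca[ri] = xyz
            elif atom.name == "C":
                self.c[ri] = xyz
            elif atom.name == "O":
                self.o[ri] = xyz
            elif atom.name in ("H", "HN") and atom.element == "H":
                self.h[ri] = xyz
                self.has_h[ri] = True

        self.complete = ~(
            np.isnan(self.n).any(axis=1)
            | np.isnan(self.ca).any(axis=1)
            | np.isnan(self.c).any(axis=1)
            | np.isnan(self.o).any(axis=1)
        )

        # segment id per residue; increments at chain boundary or CA break
        self.segment = np.zeros(nres, dtype=int)
        seg = 0
        for ri in range(1, nres):
            new_seg = self.chain_of[ri] != self.chain_of[ri - 1]
            if not new_seg and self.complete[ri] and self.complete[ri - 1]:
                if np.linalg.norm(self.ca[ri] - self.ca[ri - 1]) > CA_BREAK_CUTOFF:
                    new_seg = True
            if new_seg:
                seg += 1
            self.segment[ri] = seg

        # reconstruct missing amide hydrogens from the previous residue's C=O
        for ri in range(nres):
            if self.has_h[ri] or not self.complete[ri]:
                continue
            if ri == 0 or self.segment[ri] != self.segment[ri - 1]:
                continue  # segment N-terminus: no H
            if not self.complete[ri - 1]:
                continue
            d = self.c[ri - 1] - self.o[ri - 1]
            norm = np.linalg.norm(d)
            if norm < MIN_COINCIDENT:
                continue
            self.h[ri] = self.n[ri] + d / norm
            self.has_h[ri] = True

    def can_donate(self, ri: int) -> bool:
        return (
            self.complete[ri]
            and self.has_h[ri]
            and self.resnames[ri] != "PRO"
        )


def _hbond_map(bb: _BackboneView) -> dict[tuple[int, int], float]:
    """(acceptor_res, donor_res) -> Kabsch-Sander energy for assigned bonds."""
    nres = len(bb.resnames)
    ok = np.nonzero(bb.complete)[0]
    if ok.size == 0:
        return {}
    tree = cKDTree(bb.ca[ok])
    pairs = tree.query_pairs(9.0)  # CA-CA prefilter
    energies: dict[tuple[int, int], float] = {}
    for a_loc, b_loc in pairs:
        i, j = int(ok[a_loc]), int(ok[b_loc])
        for acc, don in ((i, j), (j, i)):
            if abs(acc - don) < 1 or not bb.can_donate(don):
                continue
            e = ks_hbond_energy(bb.c[acc], bb.o[acc], bb.n[don], bb.h[don])
            if e < HBOND_ENERGY_CUTOFF:
                energies[(acc, don)] = e
    return energies


def assign_dssp(frame: Frame, topology: Topology) -> SSAssignment:
    """DSSP-style assignment of one frame.

    Residues lacking backbone atoms are forced to C.  Chain termini that
    cannot participate in any pattern default to C.
    """
    bb = _BackboneView(frame, topology)
    nres = topology.n_residues
    energies = _hbond_map(bb)
    bonded = set(energies)

    def turn(n: int, i: int) -> bool:
        # n-turn at residue i: CO(i) ... HN(i+n), same segment
        j = i + n
        if j >= nres or bb.segment[i] != bb.segment[j]:
            return False
        return (i, j) in bonded

    codes = np.array(["C"] * nres, dtype=object)

    # --- helices: two consecutive n-turns at i-1 and i span i .. i+n-1
    helix_span: dict[str, np.ndarray] = {}
    for code, n in (("G", 3), ("H", 4), ("I", 5)):
        mask = np.zeros(nres, dtype=bool)
        for i in range(1, nres):
            if turn(n, i - 1) and turn(n, i):
                mask[i : i + n] = True
        helix_span[code] = mask

    # --- bridges
    def hb(acc: int, don: int) -> bool:
        return (acc, don) in bonded

    bridges: list[tuple[int, int, str]] = []
    for i in range(1, nres - 1):
        for j in range(i + 3, nres - 1):
            para = (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1))
            anti = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if para or anti:
                bridges.append((i, j, "P" if para else "A"))

    in_bridge = np.zeros(nres, dtype=bool)
    in_ladder = np.zeros(nres, dtype=bool)
    bridge_set = {(i, j): t for i, j, t in bridges}
    for i, j, t in bridges:
        in_bridge[i] = in_bridge[j] = True
        for di, dj in ((1, 1), (1, -1)):
            if bridge_set.get((i + di, j + dj)) == t or bridge_set.get((i - di, j - dj)) == t:
                in_ladder[i] = in_ladder[j] = True

    # --- turns: residues strictly inside any n-turn span
    in_turn = np.zeros(nres, dtype=bool)
    for n in (3, 4, 5):
        for i in range(nres):
            if turn(n, i):
                in_turn[i + 1 : i + n] = True

    # --- bends: CA curvature over i-2, i, i+2 above 70 degrees
    in_bend = np.zeros(nres, dtype=bool)
    for i in range(2, nres - 2):
        idx = [i - 2, i, i + 2]
        if not all(bb.complete[k] for k in idx):
            continue
        if bb.segment[i - 2] != bb.segment[i + 2]:
            continue
        v1 = bb.ca[i] - bb.ca[i - 2]
        v2 = bb.ca[i + 2] - bb.ca[i]
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom < MIN_COINCIDENT:
            continue
        ang = np.degrees(np.arccos(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)))
        if ang > BEND_ANGLE_DEG:
            in_bend[i] = True

    # --- combine by priority H > E > G > I > B > T > S > C
    for i in range(nres):
        if not bb.complete[i]:
            codes[i] = "C"
        elif helix_span["H"][i]:
            codes[i] = "H"
        elif in_ladder[i]:
            codes[i] = "E"
        elif helix_span["G"][i]:
            codes[i] = "G"
        elif helix_span["I"][i]:
            codes[i] = "I"
        elif in_bridge[i]:
            codes[i] = "B"
        elif in_turn[i]:
            codes[i] = "T"
        elif in_bend[i]:
            codes[i] = "S"
        else:
            codes[i] = "C"

    return SSAssignment(
        codes=list(codes), residues=topology.residues, hbond_energies=energies
    )


def ss_fraction(
    traj: Trajectory,
    chain: str,
    window: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-residue SS-class fractions over the analysis window (Fig 6 style).

    Returns a row-stochastic DataFrame indexed by residue_seq with one
    column per DSSP code plus convenience aggregates ``strand`` (E+B) and
    ``turn_bend`` (T+S).
    """
    if chain not in traj.topology.chains:
        raise ValueError(f"unknown chain {chain!r}")
    if window is None:
        window = np.arange(traj.n_frames)
    window = np.asarray(window, dtype=np.intp)
    if window.size == 0:
        raise ValueError("empty analysis window")

    res_list = traj.topology.residues
    chain_res = [k for k, r in enumerate(res_list) if r[0] == chain]
    counts = np.zeros((len(chain_res), len(SS_CODES)), dtype=float)
    code_pos = {c: k for k, c in enumerate(SS_CODES)}
    for fi in window:
        assignment = assign_dssp(traj.frames[fi], traj.topology)
        for row, ri in enumerate(chain_res):
            counts[row, code_pos[assignment.codes[ri]]] += 1
    fractions = counts / window.size
    df = pd.DataFrame(
        fractions,
        columns=list(SS_CODES),
        index=pd.Index([res_list[k][1] for k in chain_res], name="residue_seq"),
    )
    df.insert(0, "residue_name", [res_list[k][2] for k in chain_res])
    df["strand"] = df["E"] + df["B"]
    df["turn_bend"] = df["T"] + df["S"]
    return df


def codes_per_frame(
    traj: Trajectory, window: np.ndarray | None = None
) -> list[str]:
    """One code string per analysed frame (plain-text per-frame export)."""
    if window is None:
        window = np.arange(traj.n_frames)
    return [
        assign_dssp(traj.frames[fi], traj.topology).as_string()
        for fi in np.asarray(window, dtype=np.intp)
    ]
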