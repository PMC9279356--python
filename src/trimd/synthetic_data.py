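"""Toy trimer trajectory generator with planted, machine-readable ground truth.

The geometry is schematic, not chemically realistic: poly-alanine-like
backbones and a handful of decorated pseudo-atoms, laid out in widely
separated regions so the planted features cannot interfere:

* chain A — a "pocket" ring of C-alpha atoms at the origin plus a cage of
  carbon spheres that can fully bury a probe atom;
* chain B — isolated acceptor stations (carbonyl-style O atoms);
* chain C — the inhibitor: a backbone segment built from ideal dihedrals
  (alpha or 3-10 when the helix schedule is on, extended otherwise),
  donor residues (N-H) facing the chain-B acceptors, and a probe residue
  whose side-chain atom toggles between the cage centre and an exposed
  position.

Planted hydrogen bonds sit at exactly 2.8 A / 170 deg when a schedule is
on and 5.0 A when off.  Thermal jitter (sigma = 0.1 A, clipped at 3 sigma)
is added everywhere EXCEPT the contact-defining and probe/cage atoms, so
scheduled detections are recovered exactly; an unbounded jitter would
otherwise flip frames across the 3.0 A threshold.  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .structure_io import Atom, Topology, Trajectory, write_structure
from .structure_io.model import Frame

# ideal backbone geometry (A, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_C_N_CA, A_N_CA_C, A_CA_C_N, A_CA_C_O = 121.7, 111.2, 116.2, 120.8
OMEGA = 180.0

PHI_PSI = {
    "alpha": (-57.0, -47.0),
    "310": (-49.0, -26.0),
    "extended": (-140.0, 135.0),
}

CONTACT_ON_A = 2.8
CONTACT_OFF_A = 5.0
CONTACT_ANGLE_DEG = 170.0
JITTER_SIGMA_A = 0.1
JITTER_CLIP_SIGMA = 3.0

# region anchors (A); far apart so analyses cannot cross-talk
POCKET_CENTER = np.zeros(3)
HELIX_ORIGIN = np.array([9.0, 0.0, 0.0])
EJECTION_SHIFT = np.array([15.0, 0.0, 0.0])
STATION_BASE = np.array([0.0, 60.0, 0.0])
STATION_SPACING = np.array([18.0, 0.0, 0.0])
CAGE_CENTER = np.array([0.0, -60.0, 0.0])
EXPOSED_OFFSET = np.array([0.0, 0.0, 30.0])


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Standard internal-coordinate (NeRF) placement of atom d from a-b-c."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(dihedral), np.sin(angle) * np.sin(dihedral)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(phi_psi: list[tuple[float, float]]) -> dict[str, np.ndarray]:
    """Backbone N/CA/C/O coordinates for a chain of given (phi, psi) per residue."""
    n_res = len(phi_psi)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))

    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = N[0] + np.array([B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(A_N_CA_C)
    # direction making the ideal N-CA-C angle with the CA->N vector (-x)
    C[0] = CA[0] + B_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])

    for i in range(n_res - 1):
        psi = phi_psi[i][1]
        N[i + 1] = _place_atom(N[i], CA[i], C[i], B_C_N, A_CA_C_N, psi)
        CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], B_N_CA, A_C_N_CA, OMEGA)
        phi_next = phi_psi[i + 1][0]
        C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], B_CA_C, A_N_CA_C, phi_next)
    for i in range(n_res):
        psi = phi_psi[i][1]
        O[i] = _place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def _hydrogen_for_angle(
    n_pos: np.ndarray, o_pos: np.ndarray, angle_deg: float = CONTACT_ANGLE_DEG
) -> np.ndarray:
    """H at 1.0 A from the donor N such that the N-H...O angle is angle_deg."""
    u = o_pos - n_pos
    d = np.linalg.norm(u)
    u = u / d
    w = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(w, u)) > 0.9:
        w = np.array([0.0, 1.0, 0.0])
    w = w - np.dot(w, u) * u
    w /= np.linalg.norm(w)
    target = np.cos(np.deg2rad(angle_deg))

    def f(gamma: float) -> float:
        h = np.cos(gamma) * u + np.sin(gamma) * w  # unit offset from N
        hn = -h
        ho = d * u - h
        return float(np.dot(hn, ho) / np.linalg.norm(ho)) - target

    gamma = brentq(f, 1e-9, np.pi / 3)
    return n_pos + np.cos(gamma) * u + np.sin(gamma) * w


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _block_schedule(n_frames: int, fraction: float) -> np.ndarray:
    n_on = int(round(fraction * n_frames))
    mask = np.zeros(n_frames, dtype=bool)
    mask[:n_on] = True
    return mask


@dataclass
class ToyTrimerConfig:
    n_frames: int = 200
    frame_interval_ns: float = 0.1
    # planted intermolecular contacts (chain C donor -> chain B acceptor)
    contact_fractions: tuple[float, ...] = (0.7, 0.56, 0.3)
    contact_schedules: list[np.ndarray] | None = None
    # inhibitor segment
    n_helix_res: int = 12
    helix_kind: str = "alpha"  # 'alpha' | '310'
    helix_mask: np.ndarray | None = None  # default: helical in every frame
    ejection_frame: int | None = None
    # probe residue burial
    exposure_schedule: np.ndarray | None = None
    n_cage_atoms: int = 32
    jitter_sigma_A: float = JITTER_SIGMA_A
    seed: int = 0


@dataclass
class SyntheticManifest:
    """Ground truth planted by the generator; the oracle for every recovery test."""

    n_frames: int
    frame_interval_ns: float
    seed: int
    contact_schedules: dict[str, np.ndarray]
    contact_atoms: dict[str, tuple[int, int]]  # label -> (donor idx, acceptor idx)
    helix_chain: str
    helix_resid_range: tuple[int, int]
    helix_mask: np.ndarray
    helix_kind: str
    helix_selection: str
    pocket_selection: str
    ejection_frame: int | None
    probe_residue: tuple[str, int]
    exposure_schedule: np.ndarray
    jitter_sigma_A: float

    def to_jsonable(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "frame_interval_ns": self.frame_interval_ns,
            "seed": self.seed,
            "contact_schedules": {
                k: [int(v) for v in m] for k, m in sorted(self.contact_schedules.items())
            },
            "contact_atoms": {k: list(v) for k, v in sorted(self.contact_atoms.items())},
            "helix_chain": self.helix_chain,
            "helix_resid_range": list(self.helix_resid_range),
            "helix_mask": [int(v) for v in self.helix_mask],
            "helix_kind": self.helix_kind,
            "helix_selection": self.helix_selection,
            "pocket_selection": self.pocket_selection,
            "ejection_frame": self.ejection_frame,
            "probe_residue": list(self.probe_residue),
            "exposure_schedule": [int(v) for v in self.exposure_schedule],
            "jitter_sigma_A": self.jitter_sigma_A,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "SyntheticManifest":
        return cls(
            n_frames=d["n_frames"],
            frame_interval_ns=d["frame_interval_ns"],
            seed=d["seed"],
            contact_schedules={
                k: np.array(v, dtype=bool) for k, v in d["contact_schedules"].items()
            },
            contact_atoms={k: tuple(v) for k, v in d["contact_atoms"].items()},
            helix_chain=d["helix_chain"],
            helix_resid_range=tuple(d["helix_resid_range"]),
            helix_mask=np.array(d["helix_mask"], dtype=bool),
            helix_kind=d["helix_kind"],
            helix_selection=d["helix_selection"],
            pocket_selection=d["pocket_selection"],
            ejection_frame=d["ejection_frame"],
            probe_residue=(d["probe_residue"][0], int(d["probe_residue"][1])),
            exposure_schedule=np.array(d["exposure_schedule"], dtype=bool),
            jitter_sigma_A=d["jitter_sigma_A"],
        )


def make_toy_trimer(
    config: ToyTrimerConfig | None = None, seed: int | None = None
) -> tuple[Trajectory, SyntheticManifest]:
    """Generate a three-chain toy trajectory and its ground-truth manifest."""
    cfg = config or ToyTrimerConfig()
    if seed is not None:
        cfg = ToyTrimerConfig(**{**cfg.__dict__, "seed": seed})
    nf = cfg.n_frames
    if nf < 10:
        raise ValueError("need at least 10 frames")

    if cfg.contact_schedules is not None:
        schedules = [np.asarray(s, dtype=bool) for s in cfg.contact_schedules]
    else:
        schedules = [_block_schedule(nf, f) for f in cfg.contact_fractions]
    helix_mask = (
        np.asarray(cfg.helix_mask, dtype=bool)
        if cfg.helix_mask is not None
        else np.ones(nf, dtype=bool)
    )
    exposure = (
        np.asarray(cfg.exposure_schedule, dtype=bool)
        if cfg.exposure_schedule is not None
        else np.zeros(nf, dtype=bool)
    )
    for arr, label in ((helix_mask, "helix_mask"), (exposure, "exposure_schedule")):
        if arr.shape[0] != nf:
            raise ValueError(f"{label} length {arr.shape[0]} != n_frames {nf}")
    for k, s in enumerate(schedules):
        if s.shape[0] != nf:
            raise ValueError(f"contact schedule {k} length {s.shape[0]} != n_frames {nf}")

    rng = np.random.default_rng(cfg.seed)

    # ---- static topology ------------------------------------------------
    atoms: list[Atom] = []
    base_coords: list[np.ndarray] = []  # template positions, frame 0 geometry
    exempt: list[bool] = []  # True -> no thermal jitter

    def add(name, element, resname, resseq, chain, xyz, no_jitter=False) -> int:
        atoms.append(
            Atom(
                serial=len(atoms) + 1,
                name=name,
                element=element,
                residue_name=resname,
                residue_seq=resseq,
                chain_id=chain,
            )
        )
        base_coords.append(np.asarray(xyz, dtype=float))
        exempt.append(no_jitter)
        return len(atoms) - 1

    # chain A: pocket ring
    n_pocket = 6
    for k in range(n_pocket):
        ang = 2 * np.pi * k / n_pocket
        xyz = POCKET_CENTER + 4.0 * np.array([np.cos(ang), np.sin(ang), 0.0])
        add("CA", "C", "ALA", k + 1, "A", xyz)
    pocket_selection = f"chain A and resid 1-{n_pocket}"

    # chain A: cage burying the probe side-chain atom
    cage_resid = n_pocket + 1
    for k, xyz in enumerate(_fibonacci_sphere(cfg.n_cage_atoms, 2.0)):
        add(f"C{k + 1}", "C", "CAG", cage_resid, "A", CAGE_CENTER + xyz, no_jitter=True)

    # chain B: acceptor stations
    acceptor_idx: list[int] = []
    for k in range(len(schedules)):
        station = STATION_BASE + k * STATION_SPACING
        add("CA", "C", "GLY", k + 1, "B", station + np.array([0.0, 3.0, 0.0]))
        acceptor_idx.append(
            add("O", "O", "GLY", k + 1, "B", station, no_jitter=True)
        )

    # chain C: helix segment residues 1..n, donors, probe
    helix_res_lo, helix_res_hi = 1, cfg.n_helix_res
    helix_atom_start = len(atoms)
    phi_psi_hel = [PHI_PSI[cfg.helix_kind]] * cfg.n_helix_res
    bb0 = build_backbone(phi_psi_hel)
    for i in range(cfg.n_helix_res):
        for name, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            add(name, elem, "ALA", i + 1, "C", bb0[name][i] + HELIX_ORIGIN)
    helix_atom_stop = len(atoms)
    helix_selection = f"chain C and resid {helix_res_lo}-{helix_res_hi}"

    donor_idx: list[int] = []
    h_idx: list[int] = []
    donor_resids: list[int] = []
    for k in range(len(schedules)):
        station = STATION_BASE + k * STATION_SPACING
        resid = cfg.n_helix_res + 1 + k
        donor_resids.append(resid)
        n_pos = station + np.array([CONTACT_ON_A, 0.0, 0.0])
        add("CA", "C", "ASN", resid, "C", n_pos + np.array([0.0, -3.0, 0.0]))
        donor_idx.append(add("N", "N", "ASN", resid, "C", n_pos, no_jitter=True))
        h_pos = _hydrogen_for_angle(n_pos, station)
        h_idx.append(add("H", "H", "ASN", resid, "C", h_pos, no_jitter=True))

    probe_resid = cfg.n_helix_res + 1 + len(schedules)
    add("CA", "C", "TYR", probe_resid, "C",
        CAGE_CENTER + np.array([6.0, 0.0, 0.0]), no_jitter=True)
    probe_oh = add("OH", "O", "TYR", probe_resid, "C", CAGE_CENTER, no_jitter=True)

    topology = Topology(atoms)
    base = np.vstack(base_coords)
    exempt_mask = np.array(exempt, dtype=bool)

    # ---- frames ---------------------------------------------------------
    phi_psi_ext = [PHI_PSI["extended"]] * cfg.n_helix_res
    bb_by_state = {
        True: bb0,
        False: build_backbone(phi_psi_ext),
    }
    frames: list[Frame] = []
    for f in range(nf):
        coords = base.copy()

        bb = bb_by_state[bool(helix_mask[f])]
        shift = HELIX_ORIGIN.copy()
        if cfg.ejection_frame is not None and f >= cfg.ejection_frame:
            shift = shift + EJECTION_SHIFT
        cursor = helix_atom_start
        for i in range(cfg.n_helix_res):
            for name in ("N", "CA", "C", "O"):
                coords[cursor] = bb[name][i] + shift
                cursor += 1
        assert cursor == helix_atom_stop

        for k, sched in enumerate(schedules):
            if not sched[f]:
                off = np.array([CONTACT_OFF_A - CONTACT_ON_A, 0.0, 0.0])
                for idx in (donor_idx[k], h_idx[k]):
                    coords[idx] = base[idx] + off
                # donor CA follows its residue
                coords[donor_idx[k] - 1] = base[donor_idx[k] - 1] + off

        if exposure[f]:
            coords[probe_oh] = CAGE_CENTER + EXPOSED_OFFSET

        jitter = rng.normal(0.0, cfg.jitter_sigma_A, size=coords.shape)
        np.clip(
            jitter,
            -JITTER_CLIP_SIGMA * cfg.jitter_sigma_A,
            JITTER_CLIP_SIGMA * cfg.jitter_sigma_A,
            out=jitter,
        )
        jitter[exempt_mask] = 0.0
        coords = coords + jitter
        frames.append(Frame(coords=coords, time_ns=f * cfg.frame_interval_ns))

    traj = Trajectory(
        topology=topology, frames=frames, frame_interval_ns=cfg.frame_interval_ns
    )
    contact_schedules = {}
    contact_atoms = {}
    for k, sched in enumerate(schedules):
        label = f"contact_{k}"
        contact_schedules[label] = sched
        contact_atoms[label] = (donor_idx[k], acceptor_idx[k])
    manifest = SyntheticManifest(
        n_frames=nf,
        frame_interval_ns=cfg.frame_interval_ns,
        seed=cfg.seed,
        contact_schedules=contact_schedules,
        contact_atoms=contact_atoms,
        helix_chain="C",
        helix_resid_range=(helix_res_lo, helix_res_hi),
        helix_mask=helix_mask,
        helix_kind=cfg.helix_kind,
        helix_selection=helix_selection,
        pocket_selection=pocket_selection,
        ejection_frame=cfg.ejection_frame,
        probe_residue=("C", probe_resid),
        exposure_schedule=exposure,
        jitter_sigma_A=cfg.jitter_sigma_A,
    )
    return traj, manifest


DEFAULT_PARAM_TABLE = """residue_name\tatom_name\tcharge\tlj_sigma\tlj_epsilon\tradius
ASN\tN\t0.4\t3.25\t0.17\t1.65
GLY\tO\t-0.4\t2.96\t0.21\t1.60
TYR\tOH\t-0.3\t3.00\t0.21\t1.60
*\t*\t0.0\t3.40\t0.10\t1.70
"""


def write_fixture(
    traj: Trajectory, manifest: SyntheticManifest, out_dir: str | Path
) -> dict[str, Path]:
    """Write trajectory.pdb, params.tsv and manifest.json; byte-stable per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory": out / "trajectory.pdb",
        "params": out / "params.tsv",
        "manifest": out / "manifest.json",
    }
    write_structure(traj, paths["trajectory"])
    paths["params"].write_text(DEFAULT_PARAM_TABLE)
    with paths["manifest"].open("w") as fh:
        json.dump(manifest.to_jsonable(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_manifest(path: str | Path) -> SyntheticManifest:
    with Path(path).open() as fh:
        return SyntheticManifest.from_jsonable(json.load(fh))
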