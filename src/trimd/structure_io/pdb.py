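"""Multi-model PDB reading and writing.

The parser is deliberately column-strict (PDB v3 fixed columns) because the
toolkit round-trips its own fixtures and needs reproducible errors: a bad
ATOM record reports its line number, a model with a deviating atom count
reports the model index.  Phospho-residue aliases PTR/TPO are mapped to
Y2P/T2P on read.  Only blank or 'A' altloc records are kept; dropped
records are counted and logged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np

from .model import ELEMENTS, Atom, Frame, Topology, Trajectory

logger = logging.getLogger(__name__)

#: residue-name aliases normalised on read (doubly protonated phospho names).
RESNAME_ALIASES = {"PTR": "Y2P", "TPO": "T2P"}


class PDBFormatError(ValueError):
    """Raised for unparseable or internally inconsistent PDB input."""


def _guess_element(name: str, resname: str) -> str:
    """Element from the atom-name field when columns 77-78 are blank."""
    stripped = name.strip()
    # two-letter candidates only when the name starts in column 13
    for cand in (stripped[:2].capitalize(), stripped[:1].upper()):
        c = cand.strip("0123456789")
        if c in ELEMENTS:
            return c
    letters = "".join(ch for ch in stripped if ch.isalpha())
    if letters and letters[0].upper() in ELEMENTS:
        return letters[0].upper()
    raise PDBFormatError(f"cannot infer element for atom {name!r} in {resname!r}")


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, np.ndarray, str]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:21].strip()
        chain = line[21]
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element_field = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"unparseable ATOM record at line {lineno}: {exc}") from exc
    resname = RESNAME_ALIASES.get(resname, resname)
    if element_field:
        element = element_field.capitalize()
        if element not in ELEMENTS:
            element = _guess_element(name, resname)
    else:
        element = _guess_element(name, resname)
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=resname,
        residue_seq=resseq,
        chain_id=chain if chain.strip() else "A",
    )
    return atom, np.array([x, y, z]), altloc


def read_structure(
    path: Union[str, Path], frame_interval_ns: float = 0.1
) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a :class:`Trajectory`.

    A single-model file yields one frame; n MODEL blocks yield n frames
    sharing one topology.  Frame times are ``i * frame_interval_ns`` — PDB
    carries no time field, so the mapping always comes from configuration.
    """
    path = Path(path)
    atoms: list[Atom] = []
    frames_coords: list[list[np.ndarray]] = []
    current: list[np.ndarray] = []
    in_model = False
    model_count = 0
    first_model_done = False
    dropped_altloc = 0

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                atom, xyz, altloc = _parse_atom_line(line, lineno)
                if altloc not in (" ", "", "A"):
                    dropped_altloc += 1
                    continue
                if not first_model_done:
                    atoms.append(atom)
                current.append(xyz)
            elif rec.startswith("MODEL"):
                in_model = True
                model_count += 1
                if current:
                    # coordinates before the first MODEL: treat as model 0
                    frames_coords.append(current)
                    first_model_done = True
                    current = []
            elif rec.startswith("ENDMDL"):
                in_model = False
                frames_coords.append(current)
                first_model_done = True
                current = []
            # TER / REMARK / anything else: ignored

    if current:
        frames_coords.append(current)
    if not frames_coords or not atoms:
        raise PDBFormatError(f"no ATOM/HETATM records found in {path}")
    if dropped_altloc:
        logger.info("dropped %d non-'A' altloc records in %s", dropped_altloc, path)

    n = len(atoms)
    for k, fc in enumerate(frames_coords):
        if len(fc) != n:
            raise PDBFormatError(
                f"model {k + 1} has {len(fc)} atoms; model 1 has {n}"
            )

    topology = Topology(atoms)
    frames = [
        Frame(coords=np.vstack(fc), time_ns=k * frame_interval_ns)
        for k, fc in enumerate(frames_coords)
    ]
    return Trajectory(topology=topology, frames=frames, frame_interval_ns=frame_interval_ns)


def _format_atom_line(atom: Atom, xyz: np.ndarray) -> str:
    name = atom.name
    # PDB convention: 1-3 char names start in column 14 unless 2-letter element
    if len(name) < 4 and len(atom.element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"ATOM  {atom.serial:>5d} {name_field} "
        f"{atom.residue_name:<3s} {atom.chain_id}{atom.residue_seq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element.upper():>2s}\n"
    )


def write_structure(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write a trajectory as a multi-model PDB (coordinates at 1e-3 A)."""
    path = Path(path)
    top = traj.topology
    multi = traj.n_frames > 1
    with path.open("w") as fh:
        for k, frame in enumerate(traj.frames):
            if multi:
                fh.write(f"MODEL     {k + 1:>4d}\n")
            prev_chain = None
            for atom, xyz in zip(top.atoms, frame.coords):
                if prev_chain is not None and atom.chain_id != prev_chain:
                    fh.write("TER\n")
                prev_chain = atom.chain_id
                fh.write(_format_atom_line(atom, xyz))
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
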