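"""Per-atom parameter attachment from a delimited table.

The table is a header-bearing TSV with columns ``residue_name``,
``atom_name``, ``charge``, ``lj_sigma``, ``lj_epsilon``, ``radius``.
Rows are keyed by (residue_name, atom_name); a row with ``*`` in both key
columns acts as the default for unmatched atoms.  This is a stand-in for
force-field assignment, which is outside the toolkit's scope.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import replace
from pathlib import Path
from typing import Union

from .model import Topology

logger = logging.getLogger(__name__)

_COLUMNS = ("residue_name", "atom_name", "charge", "lj_sigma", "lj_epsilon", "radius")


class ParameterError(ValueError):
    """Raised when atoms cannot be matched and no default row exists."""


def _read_table(path: Union[str, Path]) -> tuple[dict, dict | None]:
    rows: dict[tuple[str, str], dict] = {}
    default = None
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _COLUMNS[:2] if c not in (reader.fieldnames or [])]
        if missing:
            raise ParameterError(f"parameter table missing columns {missing}")
        for row in reader:
            values = {}
            for col in _COLUMNS[2:]:
                raw = (row.get(col) or "").strip()
                values[col] = float(raw) if raw else None
            key = (row["residue_name"].strip().upper(), row["atom_name"].strip().upper())
            if key == ("*", "*"):
                default = values
            else:
                rows[key] = values
    return rows, default


def attach_parameters(topology: Topology, table: Union[str, Path]) -> Topology:
    """Return a new topology with charge/LJ/radius fields populated.

    Match order: exact (residue_name, atom_name), then (``*``, atom_name),
    then the (``*``, ``*``) default row.  Unmatched atoms with no default
    raise :class:`ParameterError` listing every offender.
    """
    rows, default = _read_table(table)
    new_atoms = []
    unmatched: list[str] = []
    n_defaulted = 0
    for atom in topology.atoms:
        key = (atom.residue_name.upper(), atom.name.upper())
        values = rows.get(key) or rows.get(("*", atom.name.upper()))
        if values is None:
            if default is None:
                unmatched.append(f"{atom.residue_name}/{atom.name}")
                continue
            values = default
            n_defaulted += 1
        new_atoms.append(replace(atom, **values))
    if unmatched:
        uniq = sorted(set(unmatched))
        raise ParameterError(
            "no parameters and no default row for atoms: " + ", ".join(uniq)
        )
    if n_defaulted:
        logger.info("assigned default parameters to %d atoms", n_defaulted)
    return Topology(new_atoms)
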