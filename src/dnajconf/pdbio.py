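"""PDB v3.3 multi-MODEL reading/writing and TSV matrix I/O.

The reader implements the fixed-column ATOM/HETATM layout with the dialect
rules needed for MD-derived PDB files:

* elements come from columns 77-78 when present, otherwise they are inferred
  from the atom name (names starting with a digit, e.g. ``1HB``, are
  hydrogens; the first alphabetic character gives the element, with a short
  two-letter exception list for common hetero elements on HETATM records);
* alternate locations keep the highest-occupancy copy (ties: first seen);
* insertion codes are rejected (MD output never carries them);
* chains are ignored for monomeric input; multi-chain files are an error
  unless one chain is selected explicitly.

Every frame of a multi-MODEL file must have the same atoms in the same order,
otherwise a :class:`~dnajconf.errors.TopologyError` is raised.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .errors import PDBParseError, TopologyError
from .model import Structure, Trajectory

__all__ = ["read_pdb", "write_pdb", "write_matrix", "read_matrix"]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

# two-letter elements that legitimately appear in HETATM atom names
_TWO_LETTER_HET = {"FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "SE", "CA", "NI", "CO"}


def _infer_element(name: str, record: str) -> str:
    """Element from an atom name, per the MD-output PDB dialect."""
    stripped = name.strip()
    if not stripped:
        raise ValueError("empty atom name")
    if stripped[0].isdigit():
        return "H"
    if record == "HETATM" and stripped[:2].upper() in _TWO_LETTER_HET:
        return stripped[:2].upper().capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


def _parse_atom_line(line: str, lineno: int):
    record = line[:6].strip()
    try:
        serial = int(line[6:11])
        name = line[12:16]
        altloc = line[16:17]
        resname = line[17:20].strip()
        chain = line[21:22]
        resseq = int(line[22:26])
        icode = line[26:27]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element_field = line[76:78].strip() if len(line) >= 77 else ""
    except ValueError as exc:
        raise PDBParseError(f"malformed {record} record ({exc})", lineno) from None
    if icode.strip():
        raise PDBParseError(
            f"insertion code {icode!r} not supported (residue {resseq})", lineno
        )
    if resname not in _THREE_TO_ONE:
        raise PDBParseError(f"unknown residue name {resname!r}", lineno)
    if element_field:
        element = element_field.capitalize()
    else:
        try:
            element = _infer_element(name, record)
        except ValueError as exc:
            raise PDBParseError(str(exc), lineno) from None
    return {
        "serial": serial,
        "name": name.strip(),
        "altloc": altloc.strip(),
        "resname": _THREE_TO_ONE[resname],
        "chain": chain.strip(),
        "resseq": resseq,
        "xyz": (x, y, z),
        "occupancy": occupancy,
        "element": element,
    }


def _resolve_altlocs(records: List[dict]) -> List[dict]:
    """Keep one copy per (residue, atom name): highest occupancy, ties first."""
    best: Dict[Tuple[int, str], dict] = {}
    order: List[Tuple[int, str]] = []
    for rec in records:
        key = (rec["resseq"], rec["name"])
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec["occupancy"] > best[key]["occupancy"]:
            best[key] = rec
    return [best[k] for k in order]


def _records_to_structure(records: List[dict]) -> Structure:
    records = _resolve_altlocs(records)
    return Structure(
        [r["serial"] for r in records],
        [r["name"] for r in records],
        [r["element"] for r in records],
        [r["resseq"] for r in records],
        [r["resname"] for r in records],
        np.array([r["xyz"] for r in records]).reshape(-1, 3),
    )


def read_pdb(path, chain: Optional[str] = None) -> Trajectory:
    """Read a (multi-MODEL) PDB file into a :class:`Trajectory`.

    Parameters
    ----------
    path:
        PDB file with one or more MODEL blocks (a file without MODEL records
        is a single-frame trajectory).
    chain:
        Chain identifier to keep.  Required when the file contains more than
        one chain; the default accepts single-chain (or chain-less) files.
    """
    model_records: List[List[dict]] = []
    current: List[dict] = []
    in_model = False
    seen_model = False
    chains = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                seen_model = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                model_records.append(current)
                current = []
            elif rec in ("ATOM", "HETATM"):
                parsed = _parse_atom_line(line, lineno)
                if parsed["chain"]:
                    chains.add(parsed["chain"])
                if chain is not None and parsed["chain"] and parsed["chain"] != chain:
                    continue
                current.append(parsed)
    if not seen_model:
        model_records = [current]
    elif current:
        # trailing atoms after the last ENDMDL (tolerate a missing ENDMDL)
        model_records.append(current)
    model_records = [m for m in model_records if m]
    if not model_records:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    if chain is None and len(chains) > 1:
        raise PDBParseError(
            f"{path}: multiple chains {sorted(chains)}; select one with chain="
        )
    frames = [_records_to_structure(records) for records in model_records]
    first = frames[0]
    for k, frame in enumerate(frames[1:], start=2):
        if frame.n_atoms != first.n_atoms:
            raise TopologyError(
                f"{path}: MODEL {k} has {frame.n_atoms} atoms, MODEL 1 has "
                f"{first.n_atoms}"
            )
        if not first.same_topology(frame):
            raise TopologyError(f"{path}: MODEL {k} topology differs from MODEL 1")
    return Trajectory(frames)


def _format_atom_line(serial, name, resname3, resseq, xyz, element) -> str:
    # short names are conventionally padded to start at column 14
    if len(name) < 4:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"ATOM  {serial:5d} {name_field} {resname3:>3s} A{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb(trajectory: Union[Trajectory, Structure], path) -> None:
    """Write a trajectory (or a single structure) as a multi-MODEL PDB file."""
    if isinstance(trajectory, Structure):
        trajectory = Trajectory([trajectory])
    lines: List[str] = []
    multi = trajectory.n_frames > 1
    for m, frame in enumerate(trajectory, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        for i in range(frame.n_atoms):
            code = str(frame.residue_codes[i])
            resname3 = _ONE_TO_THREE.get(code, "UNK")
            lines.append(
                _format_atom_line(
                    int(frame.serials[i]) % 100000,
                    str(frame.names[i]),
                    resname3,
                    int(frame.residue_indices[i]) % 10000,
                    frame.coords[i],
                    str(frame.elements[i]).upper(),
                )
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_matrix(obj, path) -> None:
    """Write a persistence map, sub-map or 1D profile as a TSV file.

    2D maps get residue indices as both row and column headers; 1D profiles
    become a two-column ``residue``/``value`` table.  Values are written with
    six decimals so a round-trip read reproduces them to 1e-6.
    """
    from .contacts import ContactProfile1D, PersistenceMap, SubMap

    if isinstance(obj, ContactProfile1D):
        df = pd.DataFrame(
            {"residue": obj.residues, "value": obj.values}
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
        return
    if isinstance(obj, PersistenceMap):
        rows = cols = obj.residues
        values = obj.values
    elif isinstance(obj, SubMap):
        rows, cols, values = obj.row_residues, obj.col_residues, obj.values
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite values")
    df = pd.DataFrame(values, index=rows, columns=cols)
    df.index.name = "residue"
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_matrix(path):
    """Read back a TSV written by :func:`write_matrix`.

    Returns ``(row_residues, col_residues, values)`` for a 2D map, or
    ``(residues, values)`` for a 1D profile.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) == ["residue", "value"]:
        return df["residue"].to_numpy(np.int64), df["value"].to_numpy(float)
    df = df.set_index(df.columns[0])
    rows = df.index.to_numpy(np.int64)
    cols = np.array([int(c) for c in df.columns], dtype=np.int64)
    return rows, cols, df.to_numpy(float)
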