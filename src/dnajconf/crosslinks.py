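"""Cross-linking mass-spectrometry (XLMS) restraint scoring and model ranking.

A lysine-specific cross-link implies an upper bound on the Calpha-Calpha
distance of the linked residue pair in any model consistent with the data.
Candidate structures are scored by the fraction of restraints they satisfy;
ranking is by that fraction, breaking ties by the smaller mean violation,
then input order.  The default bound of 30 Angstrom is a conventional
Calpha-Calpha reach for lysine-reactive cross-linkers and is configurable
per restraint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import RestraintError
from .model import Structure

__all__ = [
    "DEFAULT_MAX_DISTANCE",
    "Crosslink",
    "CrosslinkRecord",
    "CrosslinkReport",
    "load_crosslinks",
    "score_model",
    "rank_models",
]

DEFAULT_MAX_DISTANCE = 30.0


@dataclass(frozen=True)
class Crosslink:
    """One residue-pair distance restraint (Calpha-Calpha upper bound, A)."""

    residue_i: int
    residue_j: int
    max_distance: float = DEFAULT_MAX_DISTANCE
    expected_code: str = "K"

    def __post_init__(self):
        if self.residue_i == self.residue_j:
            raise RestraintError(
                f"self-restraint on residue {self.residue_i} is invalid"
            )
        if self.max_distance <= 0:
            raise RestraintError(
                f"max_distance must be positive, got {self.max_distance}"
            )


@dataclass(frozen=True)
class CrosslinkRecord:
    crosslink: Crosslink
    distance: float
    satisfied: bool


@dataclass(frozen=True)
class CrosslinkReport:
    records: Tuple[CrosslinkRecord, ...]
    fraction_satisfied: float
    mean_violation: Optional[float]  # mean (d - bound) among violated; None if none

    def __post_init__(self):
        if not 0.0 <= self.fraction_satisfied <= 1.0:
            raise RestraintError("fraction satisfied out of [0, 1]")


def load_crosslinks(path) -> List[Crosslink]:
    """Read a restraint TSV with columns ``res_i``, ``res_j`` and optional
    ``max_dist`` (missing values take the 30 A default)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("res_i", "res_j"):
        if col not in df.columns:
            raise RestraintError(f"{path}: missing required column {col!r}")
    out: List[Crosslink] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        try:
            i = int(row.res_i)
            j = int(row.res_j)
            if "max_dist" in df.columns and not pd.isna(row.max_dist):
                d = float(row.max_dist)
            else:
                d = DEFAULT_MAX_DISTANCE
            out.append(Crosslink(i, j, d))
        except (TypeError, ValueError, RestraintError) as exc:
            raise RestraintError(f"{path} row {row_number}: {exc}") from None
    return out


def _ca_positions(structure: Structure) -> dict:
    pos = {}
    for k in range(structure.n_atoms):
        if str(structure.names[k]) == "CA":
            pos[int(structure.residue_indices[k])] = structure.coords[k]
    return pos


def score_model(structure: Structure, restraints: Sequence[Crosslink]) -> CrosslinkReport:
    """Check each restraint against the model's Calpha-Calpha distances.

    A restraint is satisfied iff the distance is <= its bound (inclusive).
    """
    if not restraints:
        raise RestraintError("no restraints to score")
    ca = _ca_positions(structure)
    records: List[CrosslinkRecord] = []
    violations: List[float] = []
    for xl in restraints:
        for res in (xl.residue_i, xl.residue_j):
            if res not in ca:
                raise RestraintError(
                    f"restraint ({xl.residue_i}, {xl.residue_j}): residue {res} "
                    "has no CA atom in the model"
                )
        d = float(np.linalg.norm(ca[xl.residue_i] - ca[xl.residue_j]))
        ok = d <= xl.max_distance
        if not ok:
            violations.append(d - xl.max_distance)
        records.append(CrosslinkRecord(xl, d, ok))
    frac = sum(r.satisfied for r in records) / len(records)
    mean_vio = float(np.mean(violations)) if violations else None
    return CrosslinkReport(tuple(records), frac, mean_vio)


def rank_models(
    structures: Sequence[Structure], restraints: Sequence[Crosslink]
) -> List[Tuple[int, CrosslinkReport]]:
    """Order candidate models by restraint fit, best first.

    Returns ``(input_index, report)`` pairs sorted by descending fraction
    satisfied, then ascending mean violation (no violations ranks before
    any violation at equal fraction), then input order.
    """
    if not structures:
        raise RestraintError("no structures to rank")
    scored = [(k, score_model(s, restraints)) for k, s in enumerate(structures)]

    def key(item):
        k, rep = item
        vio = rep.mean_violation if rep.mean_violation is not None else -np.inf
        return (-rep.fraction_satisfied, vio, k)

    return sorted(scored, key=key)
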