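"""Geometric observables: radius of gyration, superposition, RMSF, disorder.

All coordinates are in Angstrom; the radius of gyration is additionally
reported in nm where convenient because the compaction of chaperone
conformational states is conventionally quoted in nm (for DNAJB6b the
closed/open/extended states sit near 2.1/2.6/3.1 nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DnajconfError
from .model import Structure, Trajectory

__all__ = [
    "ATOMIC_MASSES",
    "BACKBONE_NAMES",
    "RmsfProfile",
    "radius_of_gyration",
    "rg_series",
    "block_average",
    "kabsch_superpose",
    "average_structure",
    "rmsf",
    "disorder_fraction",
]

#: standard atomic masses (u) for the elements of protein heavy/light atoms
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "SE": 78.971,
    "P": 30.974,
}

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


def _masses(structure: Structure) -> np.ndarray:
    try:
        return np.array([ATOMIC_MASSES[str(e).upper()] for e in structure.elements])
    except KeyError as exc:
        raise DnajconfError(f"no standard mass for element {exc}") from None


def radius_of_gyration(structure: Structure) -> float:
    """Mass-weighted radius of gyration in Angstrom.

    Rg = sqrt( sum_i m_i |r_i - r_com|^2 / sum_i m_i ).  Works on any atom
    selection the caller passes in (heavy-only input omits the small
    hydrogen contribution, which is documented behaviour).
    """
    if structure.n_atoms == 0:
        raise DnajconfError("radius of gyration of an empty structure")
    m = _masses(structure)
    total = m.sum()
    if total <= 0:
        raise DnajconfError("zero total mass")
    com = (m[:, None] * structure.coords).sum(axis=0) / total
    sq = ((structure.coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * sq).sum() / total))


def rg_series(trajectory: Trajectory) -> np.ndarray:
    """Per-frame radius of gyration (Angstrom)."""
    return np.array([radius_of_gyration(f) for f in trajectory])


def block_average(series: Sequence[float], block: int) -> np.ndarray:
    """Means of non-overlapping consecutive blocks.

    A trailing partial block is averaged over its actual length, so the
    output covers the whole input.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise DnajconfError("cannot block-average an empty series")
    if block < 1:
        raise DnajconfError(f"block size must be >= 1, got {block}")
    out = [series[k : k + block].mean() for k in range(0, len(series), block)]
    return np.array(out)


def _selection_coords(structure: Structure, selection: Set[str]) -> np.ndarray:
    mask = np.array([n in selection for n in structure.names])
    return structure.coords[mask]


def _check_superposable(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise DnajconfError(
            f"selections differ in size: {x.shape[0]} vs {y.shape[0]} atoms"
        )
    if x.shape[0] < 3:
        raise DnajconfError("superposition needs at least 3 selected atoms")
    for pts in (x, y):
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise DnajconfError("selected atoms are collinear; superposition is degenerate")


def kabsch_superpose(
    mobile: Structure,
    reference: Structure,
    selection: Set[str] = BACKBONE_NAMES,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords @ rotation.T + translation`` maps mobile onto the reference
    frame.  The rotation is always proper (det = +1); mirror-related inputs
    therefore keep a residual RMSD instead of being reflected.  The RMSD is
    evaluated over the selection after the transform.
    """
    x = _selection_coords(mobile, selection)
    y = _selection_coords(reference, selection)
    _check_superposable(x, y)
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    with warnings.catch_warnings():
        # scipy warns for ill-conditioned/planar inputs; rank is pre-checked
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(y - yc, x - xc)
    R = rot.as_matrix()
    t = yc - xc @ R.T
    aligned = x @ R.T + t
    rmsd = float(np.sqrt(((aligned - y) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def apply_transform(structure: Structure, R: np.ndarray, t: np.ndarray) -> Structure:
    """Apply a rigid transform to all atoms of a structure."""
    return structure.with_coords(structure.coords @ np.asarray(R).T + np.asarray(t))


def average_structure(
    trajectory: Trajectory,
    selection: Set[str] = BACKBONE_NAMES,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> Structure:
    """Iterative mean structure under repeated superposition.

    Each round superposes every frame onto the running mean (over the
    selection) and recomputes the mean of all atoms; iteration stops when the
    mean moves less than ``tol`` Angstrom (mean per-atom displacement) or
    after ``max_iter`` rounds (then the last iterate is returned with a
    warning).
    """
    ref = trajectory[0]
    for _ in range(max_iter):
        acc = np.zeros_like(ref.coords)
        for frame in trajectory:
            R, t, _ = kabsch_superpose(frame, ref, selection)
            acc += frame.coords @ R.T + t
        mean_coords = acc / trajectory.n_frames
        shift = np.linalg.norm(mean_coords - ref.coords, axis=1).mean()
        ref = ref.with_coords(mean_coords)
        if shift < tol:
            return ref
    warnings.warn(
        f"average_structure did not converge to {tol} Angstrom in "
        f"{max_iter} iterations",
        stacklevel=2,
    )
    return ref


@dataclass(frozen=True)
class RmsfProfile:
    """Per-residue backbone root-mean-square fluctuation (Angstrom)."""

    residues: np.ndarray
    values: np.ndarray
    reference: Structure

    def value_at(self, residue: int) -> float:
        idx = {int(r): k for k, r in enumerate(self.residues)}
        return float(self.values[idx[residue]])


def rmsf(
    trajectory: Trajectory,
    reference: Optional[Structure] = None,
    selection: Set[str] = BACKBONE_NAMES,
) -> RmsfProfile:
    """Backbone RMSF after rigid-body superposition onto a reference.

    Every frame is superposed onto the reference over ``selection``; the
    fluctuation of each selected atom is its RMS deviation from its own
    time-mean position, and residue values are the RMS over that residue's
    selected atoms.  The default reference is the iterative average
    structure of the trajectory.
    """
    if reference is None:
        reference = average_structure(trajectory, selection)
    mask = np.array([n in selection for n in trajectory[0].names])
    if not mask.any():
        raise DnajconfError("selection matches no atoms")
    aligned = np.empty((trajectory.n_frames, int(mask.sum()), 3))
    for k, frame in enumerate(trajectory):
        R, t, _ = kabsch_superpose(frame, reference, selection)
        aligned[k] = frame.coords[mask] @ R.T + t
    mean_pos = aligned.mean(axis=0)
    per_atom_msd = ((aligned - mean_pos) ** 2).sum(axis=2).mean(axis=0)
    res_of_atom = trajectory[0].residue_indices[mask]
    residues = np.unique(res_of_atom)
    values = np.array(
        [np.sqrt(per_atom_msd[res_of_atom == r].mean()) for r in residues]
    )
    return RmsfProfile(residues=residues, values=values, reference=reference)


_SS_ALPHABET = set("HGIEBbTC")
_DISORDERED = set("TC")


def disorder_fraction(ss_labels: str, region: Optional[Tuple[int, int]] = None,
                      first_residue: int = 1) -> Tuple[float, float]:
    """(ordered, disordered) fractions from STRIDE-style per-residue letters.

    Coils (C) and turns (T) count as disordered; helix (H, G, I) and strand
    or bridge (E, B, b) count as ordered.  ``region`` optionally restricts
    the computation to an inclusive residue interval, with ``first_residue``
    giving the residue index of the first letter.
    """
    labels = str(ss_labels)
    if region is not None:
        a, b = region
        lo = a - first_residue
        hi = b - first_residue + 1
        if lo < 0 or hi > len(labels):
            raise DnajconfError(
                f"labels (length {len(labels)}, starting at residue "
                f"{first_residue}) do not cover region {region}"
            )
        labels = labels[lo:hi]
    if not labels:
        raise DnajconfError("empty secondary-structure label string")
    unknown = set(labels) - _SS_ALPHABET
    if unknown:
        raise DnajconfError(f"unknown secondary-structure letters: {sorted(unknown)}")
    disordered = sum(1 for ch in labels if ch in _DISORDERED) / len(labels)
    return 1.0 - disordered, disordered
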