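"""In-memory containers: atoms, structures, trajectories and the domain scheme.

A :class:`Structure` is a flat, numpy-backed table of heavy (or all) atoms of a
single conformer; a :class:`Trajectory` is an ordered list of structures that
share one topology (atom count, names, residue assignment).  The
:class:`DomainScheme` holds named, inclusive 1-based residue intervals for the
domains and functional regions of a multi-domain chaperone chain; its defaults
encode the DNAJB6b-style layout of a 241-residue chain:
J-domain 1-74, G/F1 75-108, G/F2 109-131, S/T 132-188, CTD 189-241.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .errors import SchemeError, TopologyError

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "DomainScheme",
    "select_heavy",
]


@dataclass(frozen=True)
class Atom:
    """One heavy (or hydrogen) atom of a protein chain.

    Coordinates are in Angstrom.  ``residue_index`` is the 1-based residue
    sequence number; ``residue_code`` the one-letter amino-acid code.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_code: str
    coordinates: np.ndarray

    def __post_init__(self):
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if self.residue_index < 1:
            raise ValueError(
                f"residue_index must be >= 1, got {self.residue_index}"
            )
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be a finite 3-vector")
        object.__setattr__(self, "coordinates", coords)


class Structure:
    """A single conformer stored as parallel numpy arrays.

    Atoms are kept sorted by (residue_index, serial); all atoms of one residue
    must share a residue code.
    """

    def __init__(
        self,
        serials: Sequence[int],
        names: Sequence[str],
        elements: Sequence[str],
        residue_indices: Sequence[int],
        residue_codes: Sequence[str],
        coords: np.ndarray,
    ):
        self.serials = np.asarray(serials, dtype=np.int64)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=np.int64)
        self.residue_codes = np.asarray(residue_codes, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = len(self.serials)
        for arr, label in [
            (self.names, "names"),
            (self.elements, "elements"),
            (self.residue_indices, "residue_indices"),
            (self.residue_codes, "residue_codes"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{label} length {len(arr)} != {n} atoms")
        if self.coords.shape[0] != n:
            raise ValueError("coords row count does not match atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if n and np.any(self.residue_indices < 1):
            raise ValueError("residue indices must be >= 1")
        # enforce sorting invariant (stable, so ties keep input order)
        order = np.lexsort((self.serials, self.residue_indices))
        if not np.all(order == np.arange(n)):
            for attr in (
                "serials",
                "names",
                "elements",
                "residue_indices",
                "residue_codes",
            ):
                setattr(self, attr, getattr(self, attr)[order])
            self.coords = self.coords[order]
        # one residue, one code
        for res in np.unique(self.residue_indices):
            codes = set(self.residue_codes[self.residue_indices == res])
            if len(codes) > 1:
                raise ValueError(
                    f"residue {res} carries multiple residue codes: {sorted(codes)}"
                )

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom]) -> "Structure":
        return cls(
            [a.serial for a in atoms],
            [a.name for a in atoms],
            [a.element for a in atoms],
            [a.residue_index for a in atoms],
            [a.residue_code for a in atoms],
            np.array([a.coordinates for a in atoms]).reshape(-1, 3),
        )

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    def __len__(self) -> int:
        return self.n_atoms

    def atoms(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield Atom(
                int(self.serials[i]),
                str(self.names[i]),
                str(self.elements[i]),
                int(self.residue_indices[i]),
                str(self.residue_codes[i]),
                self.coords[i].copy(),
            )

    def subset(self, mask: np.ndarray) -> "Structure":
        """Sub-structure from a boolean atom mask, order preserved."""
        mask = np.asarray(mask, dtype=bool)
        return Structure(
            self.serials[mask],
            self.names[mask],
            self.elements[mask],
            self.residue_indices[mask],
            self.residue_codes[mask],
            self.coords[mask],
        )

    def select_names(self, names) -> "Structure":
        names = set(names)
        return self.subset(np.array([n in names for n in self.names]))

    def residue_numbers(self) -> np.ndarray:
        """Sorted unique residue indices present."""
        return np.unique(self.residue_indices)

    def residue_code_map(self) -> Dict[int, str]:
        out: Dict[int, str] = {}
        for res, code in zip(self.residue_indices, self.residue_codes):
            out[int(res)] = str(code)
        return out

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Same topology, new coordinates."""
        return Structure(
            self.serials,
            self.names,
            self.elements,
            self.residue_indices,
            self.residue_codes,
            coords,
        )

    def same_topology(self, other: "Structure") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.names, other.names)
            and np.array_equal(self.residue_indices, other.residue_indices)
            and np.array_equal(self.residue_codes, other.residue_codes)
        )


class Trajectory:
    """An ordered list of same-topology frames.

    ``frame_interval`` is the (optional) time per frame in arbitrary units; the
    analysis itself treats frames as equally spaced and never needs a unit.
    """

    def __init__(self, frames: Sequence[Structure], frame_interval: Optional[float] = None):
        frames = list(frames)
        if not frames:
            raise TopologyError("a trajectory needs at least one frame")
        first = frames[0]
        for k, frame in enumerate(frames[1:], start=2):
            if frame.n_atoms != first.n_atoms:
                raise TopologyError(
                    f"frame {k} has {frame.n_atoms} atoms, expected {first.n_atoms}"
                )
            if not first.same_topology(frame):
                raise TopologyError(f"frame {k} topology differs from frame 1")
        self.frames: List[Structure] = frames
        self.frame_interval = frame_interval

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)

    def __getitem__(self, i) -> Structure:
        return self.frames[i]

    def coords_stack(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array."""
        return np.stack([f.coords for f in self.frames])


#: default named regions (inclusive 1-based intervals) of the 241-residue chain
DEFAULT_REGIONS: Dict[str, Tuple[int, int]] = {
    "J": (1, 74),
    "GF1": (75, 108),
    "GF2": (109, 131),
    "ST": (132, 188),
    "CTD": (189, 241),
    "helixV": (96, 104),
    "helicesII_III": (16, 56),
    "HPD": (31, 33),
    "AR2_GF": (118, 125),
    "AR2_J": (1, 28),
}

_TOP_LEVEL = ("J", "GF1", "GF2", "ST", "CTD")


@dataclass
class DomainScheme:
    """Named residue intervals for domains and functional regions.

    The four top-level domains (J, G/F = G/F1+G/F2, S/T, CTD) must be disjoint
    and ordered along the sequence, with G/F1 and G/F2 adjacent.
    """

    regions: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )

    def __post_init__(self):
        self.regions = {k: (int(v[0]), int(v[1])) for k, v in self.regions.items()}
        for name, (a, b) in self.regions.items():
            if a < 1 or b < a:
                raise SchemeError(f"region {name}: invalid interval [{a}, {b}]")
        missing = [n for n in _TOP_LEVEL if n not in self.regions]
        if missing:
            raise SchemeError(f"scheme missing required regions: {missing}")
        ivals = [self.regions[n] for n in _TOP_LEVEL]
        for (a1, b1), (a2, b2) in zip(ivals, ivals[1:]):
            if a2 <= b1:
                raise SchemeError(
                    "top-level domains must be disjoint and ordered along the chain"
                )
        gf1, gf2 = self.regions["GF1"], self.regions["GF2"]
        if gf2[0] != gf1[1] + 1:
            raise SchemeError("GF1 and GF2 must be adjacent")

    @classmethod
    def default(cls) -> "DomainScheme":
        return cls()

    @classmethod
    def from_file(cls, path) -> "DomainScheme":
        """Load a scheme from YAML or JSON, overriding the defaults.

        The file maps region names to two-element [start, end] lists; regions
        not mentioned keep their default interval.
        """
        with open(path) as fh:
            text = fh.read()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise SchemeError(f"{path}: expected a mapping of region -> [start, end]")
        regions = dict(DEFAULT_REGIONS)
        for name, ival in data.items():
            if not (isinstance(ival, (list, tuple)) and len(ival) == 2):
                raise SchemeError(f"{path}: region {name} must be [start, end]")
            regions[str(name)] = (int(ival[0]), int(ival[1]))
        return cls(regions)

    def to_dict(self) -> Dict[str, List[int]]:
        return {k: [a, b] for k, (a, b) in self.regions.items()}

    def region(self, name: str) -> Tuple[int, int]:
        try:
            return self.regions[name]
        except KeyError:
            raise SchemeError(f"scheme has no region named {name!r}") from None

    def gf(self) -> Tuple[int, int]:
        """The full G/F interval (G/F1 union G/F2)."""
        return (self.regions["GF1"][0], self.regions["GF2"][1])

    @property
    def n_residues(self) -> int:
        return max(b for _, b in self.regions.values())


def select_heavy(structure: Structure) -> Structure:
    """Return the hydrogen-free subset of a structure, order preserved.

    Hydrogens are excluded from all contact analysis; this is the single
    chokepoint where that selection happens.  Idempotent.
    """
    mask = np.array([str(e).upper() != "H" for e in structure.elements])
    return structure.subset(mask)
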