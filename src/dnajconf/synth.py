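"""Synthetic multi-domain conformers for testing the analysis stack.

The generator lays out a 241-residue virtual-Calpha chain whose interdomain
contact pattern realizes a prescribed conformational state:

* *ladders* -- pairs of short antiparallel chain segments placed one contact
  pitch apart, with pseudo side-chain beads pointing at each other -- create
  the designed residue-residue contacts: anchor region 1 (helix V 96-104
  against helices II/III residues 31-39), anchor region 2 (118-125 against
  21-28), a G/F2 x S/T ladder (109-114 against 132-137, half-step offset so
  most residues touch two partners), and, in the closed state only, a
  G/F1 x CTD ladder (80-84 against 196-200);
* *loops* -- arclength-resampled polylines through hand-placed waypoints --
  route the chain between ladders while keeping state-relevant domain pairs
  (G/F vs CTD, G/F2 vs S/T) far apart wherever no contact is intended;
* the open state moves the whole CTD block away from G/F1, and the extended
  state additionally moves the S/T + CTD blocks away from G/F2, so the
  classifier's rules discriminate the three states exactly as designed.

Every residue carries five heavy atoms (backbone N, CA, C, O plus one
pseudo side-chain bead "CB", including glycine).  No physics is claimed:
the chain is a geometric fixture whose purpose is to exercise residue-level
contact logic with known ground truth.  All randomness is seeded; the same
config and seed reproduce bit-identical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .contacts import frame_contacts, interdomain_count
from .crosslinks import Crosslink
from .errors import GenerationError
from .model import DomainScheme, Structure, Trajectory
from .states import StateLabel, classify_frame

__all__ = [
    "GeneratorConfig",
    "default_sequence",
    "generate_conformer",
    "generate_trajectory",
    "generate_crosslink_truth",
]

_BOND = 3.8  # virtual Calpha-Calpha spacing the layout is designed for


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-conformer generator.

    ``seed`` fixes all randomness.  ``conformer_jitter`` (A) perturbs the
    deterministic state template in :func:`generate_conformer` so different
    seeds give different conformers; ``jitter_sigma`` (A) is the per-frame
    Gaussian jitter of :func:`generate_trajectory`.  ``bond_length`` scales
    the whole layout relative to its design spacing of 3.8 A.
    """

    n_residues: int = 241
    sequence: Optional[str] = None
    bond_length: float = 3.8
    jitter_sigma: float = 0.2
    conformer_jitter: float = 0.15
    self_avoid_min: float = 2.5
    max_retries: int = 25
    st_phe_enrichment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 241:
            raise GenerationError(
                "chain length must cover the 241-residue domain scheme"
            )
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise GenerationError(
                f"sequence length {len(self.sequence)} != n_residues {self.n_residues}"
            )
        if self.bond_length <= 0:
            raise GenerationError("bond_length must be positive")


def default_sequence(n_residues: int = 241, st_phe_enrichment: bool = True) -> str:
    """Deterministic default residue identities.

    Poly-alanine background with functional placements: the HPD motif at
    31-33, phenylalanines at the study-motivated G/F positions (91, 93, 100,
    103, 104), an F/G-rich G/F2, an S/T-rich substrate domain (optionally
    F-enriched), and lysines sprinkled through the chain for cross-link
    fixtures.
    """
    seq = ["A"] * n_residues

    def put(pairs):
        for pos, code in pairs:
            if pos <= n_residues:
                seq[pos - 1] = code

    # J-domain: HPD motif, ladder identities on 31-39, scattered K/E/D
    put([(10, "K"), (18, "E"), (44, "K"), (50, "E"), (60, "D")])
    put([(31, "H"), (32, "P"), (33, "D"), (34, "L"), (35, "A"),
         (36, "K"), (37, "F"), (38, "L"), (39, "L")])
    # AR2 J-side identities (21-28)
    put([(21, "A"), (22, "S"), (23, "K"), (24, "V"), (25, "R"),
         (26, "L"), (27, "T"), (28, "A")])
    # G/F1: glycine-rich linker, helix V 96-104, GF1 x CTD ladder 80-84
    for i in range(75, 96):
        seq[i - 1] = "G"
    put([(80, "L"), (81, "A"), (82, "V"), (83, "L"), (84, "A")])
    put([(91, "F"), (93, "F")])
    put([(96, "V"), (97, "A"), (98, "L"), (99, "E"), (100, "F"),
         (101, "A"), (102, "R"), (103, "F"), (104, "F")])
    # G/F2: F/G alternation on the S/T-facing ladder, AR2 G/F side 118-125
    for i in range(105, 132):
        seq[i - 1] = "G"
    put([(109, "G"), (110, "F"), (111, "G"), (112, "F"), (113, "G"), (114, "F")])
    put([(118, "G"), (119, "A"), (120, "L"), (121, "Y"),
         (122, "G"), (123, "F"), (124, "A"), (125, "G")])
    # S/T domain: serine/threonine alternation, ladder F's, K's for XLMS
    for i in range(132, 189):
        seq[i - 1] = "S" if i % 2 == 0 else "T"
    put([(132, "F"), (134, "F"), (136, "F")])
    if st_phe_enrichment:
        put([(147, "F"), (152, "F"), (160, "F")])
    put([(150, "K"), (165, "K"), (180, "K")])
    # CTD: mixed aliphatics with K/E sprinkles
    for i in range(189, n_residues + 1):
        seq[i - 1] = "AVL"[i % 3]
    put([(196, "V"), (197, "L"), (198, "F"), (199, "A")])
    put([(200, "K"), (205, "E"), (210, "K"), (215, "E"),
         (220, "K"), (230, "K"), (240, "K")])
    return "".join(seq)


# ---------------------------------------------------------------------------
# layout construction


def _resample_polyline(waypoints: List[np.ndarray], n: int) -> np.ndarray:
    """n points evenly spaced in arclength along the open polyline,
    excluding both endpoints (fractions k/(n+1), k = 1..n)."""
    pts = np.asarray(waypoints, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    out = np.empty((n, 3))
    for k in range(1, n + 1):
        s = total * k / (n + 1)
        j = int(np.searchsorted(cum, s, side="right") - 1)
        j = min(j, len(seg) - 1)
        f = (s - cum[j]) / seg[j] if seg[j] > 0 else 0.0
        out[k - 1] = pts[j] + f * (pts[j + 1] - pts[j])
    return out


def _bridge(p_from: np.ndarray, p_to: np.ndarray, n: int, bulge: float = 0.0) -> np.ndarray:
    """n intermediate points between two fixed residues, with an optional
    sinusoidal out-of-plane (z) bulge to gain clearance/path length."""
    fracs = np.arange(1, n + 1) / (n + 1)
    pts = p_from[None, :] + fracs[:, None] * (p_to - p_from)[None, :]
    pts[:, 2] += bulge * np.sin(np.pi * fracs)
    return pts


_LADDER_SIDE: Dict[Tuple[int, int], Tuple[float, float, float]] = {
    # residue range -> pseudo side-chain direction (unit vector)
    (31, 39): (0.0, +1.0, 0.0),   # AR1 J side, partner above at y=+5
    (96, 104): (0.0, -1.0, 0.0),  # helix V, partner below
    (21, 26): (0.0, -1.0, 0.0),   # AR2 J side, partner below at y=-10.4
    (28, 28): (-1.0, 0.0, 0.0),   # J dock onto the G/F1 C-terminal linker
    (118, 125): (0.0, +1.0, 0.0), # AR2 G/F side, partner above
    (109, 114): (0.0, -1.0, 0.0), # G/F2 ladder, partner below
    (132, 137): (0.0, +1.0, 0.0), # S/T ladder, partner above
    (80, 84): (0.0, -1.0, 0.0),   # G/F1 ladder, partner below
    (196, 200): (0.0, +1.0, 0.0), # CTD ladder, partner above
}


def _intended_pairs(state: StateLabel) -> Set[Tuple[int, int]]:
    pairs: Set[Tuple[int, int]] = set()
    pairs.update((i, 135 - i) for i in range(31, 40))      # AR1
    pairs.update((i, 146 - i) for i in range(21, 27))      # AR2 ladder
    # J residues 27-30 arc over the G/F1 C-terminal linker to dock residue
    # 28 onto residue 108 (J contact at the last G/F1 residue)
    pairs.update({(28, 107), (28, 108), (29, 107)})
    # G/F2 x S/T half-step ladder: |x_i - x_j| = 1.9 partners
    for i in range(109, 115):
        xi = 34.2 - (i - 109) * _BOND
        for j in range(132, 138):
            xj = 17.1 + (j - 132) * _BOND
            if abs(xi - xj) < 2.0:
                pairs.add((i, j))
    if state == StateLabel.CLOSED:
        pairs.update((i, 280 - i) for i in range(80, 85))  # G/F1 x CTD
    return pairs


def _ca_template(state: StateLabel, n_residues: int) -> np.ndarray:
    """Deterministic Calpha layout for one state (design spacing, A)."""
    b = _BOND
    st_shift = -12.0 if state == StateLabel.EXTENDED else 0.0
    if state == StateLabel.CLOSED:
        ctd_shift = 0.0
    elif state == StateLabel.OPEN:
        ctd_shift = -12.0
    else:
        ctd_shift = -24.0

    pos = np.zeros((n_residues, 3))

    def P(i):
        return pos[i - 1]

    def set_row(i0, i1, x0, y, direction):
        for i in range(i0, i1 + 1):
            pos[i - 1] = (x0 + direction * (i - i0) * b, y, 0.0)

    def poly(waypoints, n):
        return _resample_polyline([np.asarray(p, float) for p in waypoints], n)

    # J-domain N-terminal row (carries the AR2 J side 21-26); residues
    # 27-30 descend past the AR2 G/F strand so residue 28 docks onto the
    # G/F1 C-terminal linker (105-108), giving G/F1 J contacts up to its
    # last residue as in the real chain
    set_row(1, 26, 30.4 - 27 * b, -5.0, +1.0)
    pos[26] = (29.5, -8.0, 6.0)     # residue 27
    pos[27] = (37.5, -14.3, 0.0)    # residue 28, CB toward residue 108
    pos[28] = (37.0, -9.0, 6.5)     # residue 29
    pos[29] = (32.0, -4.5, 6.5)     # residue 30
    # helices II/III ladder strand
    set_row(31, 39, 30.4, 0.0, -1.0)
    # long J -> G/F1 loop routed around the chain's left flank
    set_row(80, 84, -50.2, -30.0, +1.0)
    pos[39:79] = poly(
        [P(39), (-20.0, 8.0, 0.0), (-60.0, 8.0, 0.0), (-84.0, -4.0, 0.0),
         (-80.0, -22.0, 0.0), (-62.0, -28.0, 0.0), P(80)], 40)
    # helix V ladder strand; the connector climbs out of plane to clear
    # the J rows it crosses
    set_row(96, 104, 0.0, 5.0, +1.0)
    pos[84:95] = poly(
        [P(84), (-28.0, -16.0, 8.0), (-16.0, -4.0, 9.0), (-4.0, 4.0, 6.0),
         P(96)], 11)
    # G/F2: S/T-facing ladder then the AR2 strand
    set_row(109, 114, 34.2, -20.0, -1.0)
    pos[104:108] = poly(
        [P(104), (37.0, -2.0, 4.0), (34.0, -13.0, 2.0), P(109)], 4)
    set_row(118, 125, 30.4, -10.4, -1.0)
    pos[114:117] = _bridge(P(114), P(118), 3, bulge=-2.5)  # 115-117
    # S/T block (shifts away from G/F2 in the extended state)
    set_row(132, 137, 17.1, -24.6 + st_shift, +1.0)
    pos[125:131] = poly(
        [P(125), (7.0, -16.0, 6.0), P(132) + np.array([-3.0, -4.0, 4.0]),
         P(132)], 6)
    set_row(141, 155, 36.1, -38.0 + st_shift, -1.0)
    pos[137:140] = _bridge(P(137), P(141), 3, bulge=2.0)
    set_row(159, 173, -17.1, -48.0 + st_shift, +1.0)
    pos[155:158] = _bridge(P(155), P(159), 3, bulge=2.5)
    set_row(177, 188, 36.1, -58.0 + st_shift, -1.0)
    pos[173:176] = _bridge(P(173), P(177), 3, bulge=2.5)
    # CTD block (docks onto G/F1 only in the closed state); the S/T -> CTD
    # connector swings left and out of plane to clear the S/T rows
    set_row(196, 200, -35.0, -35.0 + ctd_shift, -1.0)
    pos[188:195] = poly(
        [P(188), P(188) + np.array([-14.3, -4.0, 5.0]),
         P(196) + np.array([1.0, -13.0, 5.0]), P(196)], 7)
    set_row(204, 214, -55.0, -45.0 + ctd_shift, -1.0)
    pos[200:203] = _bridge(P(200), P(204), 3, bulge=2.0)
    set_row(218, 228, -93.0, -55.0 + ctd_shift, +1.0)
    pos[214:217] = _bridge(P(214), P(218), 3, bulge=2.5)
    set_row(232, 241, -55.0, -65.0 + ctd_shift, -1.0)
    pos[228:231] = _bridge(P(228), P(232), 3, bulge=2.5)
    if n_residues > 241:
        # extra residues extend the final CTD row
        set_row(242, n_residues, pos[240, 0] - b, -65.0 + ctd_shift, -1.0)
    return pos


def _side_direction(i: int) -> Optional[np.ndarray]:
    for (a, b), direction in _LADDER_SIDE.items():
        if a <= i <= b:
            return np.array(direction, dtype=float)
    return None


def _build_structure(ca: np.ndarray, sequence: str) -> Structure:
    """Backbone + pseudo side-chain atoms from Calpha positions.

    N and C sit 1.2 A along the local chain tangent, O is offset
    perpendicular to the backbone plane, and CB sits 1.2 A along the
    residue's side direction (toward the ladder partner where one exists,
    otherwise out of the layout plane).
    """
    n = len(ca)
    zhat = np.array([0.0, 0.0, 1.0])
    xhat = np.array([1.0, 0.0, 0.0])
    serials, names, elements, res_idx, res_codes, coords = [], [], [], [], [], []
    serial = 1
    for i in range(1, n + 1):
        p = ca[i - 1]
        lo = ca[max(0, i - 2)]
        hi = ca[min(n - 1, i)]
        t = hi - lo
        norm = np.linalg.norm(t)
        t = t / norm if norm > 1e-9 else xhat.copy()
        s = _side_direction(i)
        if s is None:
            s = zhat - np.dot(zhat, t) * t
            if np.linalg.norm(s) < 1e-6:
                s = xhat - np.dot(xhat, t) * t
            s = s / np.linalg.norm(s)
        u = np.cross(t, s)
        un = np.linalg.norm(u)
        u = u / un if un > 1e-9 else zhat
        atom_xyz = {
            "N": p - 1.2 * t,
            "CA": p,
            "C": p + 1.2 * t,
            "O": p + 1.2 * t + 1.0 * u,
            "CB": p + 1.2 * s,
        }
        for name in ("N", "CA", "C", "O", "CB"):
            serials.append(serial)
            names.append(name)
            elements.append(name[0] if name != "CA" and name != "CB" else "C")
            res_idx.append(i)
            res_codes.append(sequence[i - 1])
            coords.append(atom_xyz[name])
            serial += 1
    return Structure(serials, names, elements, res_idx, res_codes, np.array(coords))


# ---------------------------------------------------------------------------
# verification


def _self_avoidance_ok(
    structure: Structure,
    intended: Set[Tuple[int, int]],
    min_dist: float,
) -> bool:
    tree = cKDTree(structure.coords)
    close = tree.query_pairs(r=min_dist, output_type="ndarray")
    if not len(close):
        return True
    res = structure.residue_indices
    for a, b in close:
        i, j = int(res[a]), int(res[b])
        lo, hi = min(i, j), max(i, j)
        if hi - lo >= 4 and (lo, hi) not in intended:
            return False
    return True


def _state_conditions_ok(structure: Structure, state: StateLabel, scheme: DomainScheme) -> bool:
    cs = frame_contacts(structure)
    if classify_frame(cs, scheme) != state:
        return False
    ar1 = sum(
        1 for p in cs.pairs
        if _in(p, scheme.region("helicesII_III"), scheme.region("helixV"))
    )
    ar2 = sum(
        1 for p in cs.pairs
        if _in(p, scheme.region("AR2_J"), scheme.region("AR2_GF"))
    )
    if ar1 == 0 or ar2 == 0:
        return False
    gf1_ctd = interdomain_count(cs, scheme.region("GF1"), scheme.region("CTD"))
    gf_ctd = interdomain_count(cs, scheme.gf(), scheme.region("CTD"))
    gf2_st = interdomain_count(cs, scheme.region("GF2"), scheme.region("ST"))
    if state == StateLabel.CLOSED:
        return gf1_ctd >= 1 and gf2_st >= 4
    if state == StateLabel.OPEN:
        return gf_ctd == 0 and gf2_st >= 4
    return gf_ctd == 0 and gf2_st <= 3


def _in(pair, regionA, regionB) -> bool:
    i, j = pair
    (a1, a2), (b1, b2) = regionA, regionB
    return (a1 <= i <= a2 and b1 <= j <= b2) or (b1 <= i <= b2 and a1 <= j <= a2)


# ---------------------------------------------------------------------------
# public generators


def _resolve_sequence(config: GeneratorConfig) -> str:
    if config.sequence is not None:
        return config.sequence
    return default_sequence(config.n_residues, config.st_phe_enrichment)


def _make_frame(
    state: StateLabel,
    config: GeneratorConfig,
    scheme: DomainScheme,
    rng: np.random.Generator,
    sigma: float,
    check_self_avoidance: bool,
) -> Structure:
    template = _ca_template(state, config.n_residues) * (config.bond_length / _BOND)
    sequence = _resolve_sequence(config)
    intended = _intended_pairs(state)
    for _ in range(max(1, config.max_retries)):
        ca = template if sigma == 0 else template + rng.normal(0.0, sigma, template.shape)
        structure = _build_structure(ca, sequence)
        if check_self_avoidance and not _self_avoidance_ok(
            structure, intended, config.self_avoid_min
        ):
            continue
        if _state_conditions_ok(structure, state, scheme):
            return structure
        if sigma == 0:
            break  # deterministic template failed; retrying cannot help
    raise GenerationError(
        f"could not place a valid {state.value} conformer after "
        f"{config.max_retries} attempts; relax jitter or bond_length"
    )


def generate_conformer(
    config: GeneratorConfig,
    target: StateLabel,
    scheme: Optional[DomainScheme] = None,
) -> Structure:
    """One heavy-atom conformer whose contacts classify as ``target``.

    The deterministic state template is perturbed by seeded Gaussian jitter
    (``config.conformer_jitter``); the result is verified to be
    self-avoiding (minimum heavy-atom separation ``self_avoid_min`` between
    residues >= 4 apart in sequence, intended contact pairs exempt), to
    contain anchor-region 1 and 2 contacts, and to satisfy the target
    state's interdomain contact-count conditions.
    """
    scheme = scheme or DomainScheme.default()
    rng = np.random.default_rng(config.seed)
    return _make_frame(
        StateLabel(target), config, scheme, rng,
        sigma=config.conformer_jitter, check_self_avoidance=True,
    )


def generate_trajectory(
    config: GeneratorConfig,
    state_sequence: Sequence[StateLabel],
    frames_per_state: int,
    scheme: Optional[DomainScheme] = None,
) -> Trajectory:
    """Concatenated frames realizing a prescribed state sequence.

    Each segment draws ``frames_per_state`` frames around its state's
    template with per-frame Gaussian jitter (``config.jitter_sigma``),
    re-drawn until the frame still classifies as the segment's state.
    Topology is constant across all frames.
    """
    if not state_sequence:
        raise GenerationError("state_sequence must be non-empty")
    if frames_per_state < 1:
        raise GenerationError("frames_per_state must be >= 1")
    scheme = scheme or DomainScheme.default()
    rng = np.random.default_rng(config.seed)
    frames: List[Structure] = []
    for state in state_sequence:
        for _ in range(frames_per_state):
            frames.append(
                _make_frame(
                    StateLabel(state), config, scheme, rng,
                    sigma=config.jitter_sigma, check_self_avoidance=False,
                )
            )
    return Trajectory(frames)


def generate_crosslink_truth(
    structure: Structure,
    n: int,
    satisfied_fraction: float,
    seed: int,
) -> List[Crosslink]:
    """Restraints with a planted satisfied fraction for scorer round-trips.

    Picks ``n`` distinct lysine-lysine residue pairs and sets each bound
    above or below the measured Calpha-Calpha distance so that exactly
    ``round(n * satisfied_fraction)`` restraints are satisfied.
    """
    if not 0.0 <= satisfied_fraction <= 1.0:
        raise GenerationError("satisfied_fraction must be in [0, 1]")
    codes = structure.residue_code_map()
    lys = sorted(r for r, c in codes.items() if c == "K")
    pairs = [(i, j) for k, i in enumerate(lys) for j in lys[k + 1 :]]
    if n > len(pairs):
        raise GenerationError(
            f"requested {n} restraints but only {len(pairs)} lysine pairs exist"
        )
    rng = np.random.default_rng(seed)
    chosen = [pairs[k] for k in rng.choice(len(pairs), size=n, replace=False)]
    ca = {int(structure.residue_indices[k]): structure.coords[k]
          for k in range(structure.n_atoms) if str(structure.names[k]) == "CA"}
    n_sat = int(round(n * satisfied_fraction))
    out: List[Crosslink] = []
    for k, (i, j) in enumerate(chosen):
        d = float(np.linalg.norm(ca[i] - ca[j]))
        if k < n_sat:
            bound = d + rng.uniform(2.0, 8.0)
        else:
            bound = d * rng.uniform(0.3, 0.8)
        out.append(Crosslink(i, j, bound))
    return out
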