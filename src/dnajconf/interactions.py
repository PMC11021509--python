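"""Residue-identity based interaction typing and anchor-region maps.

Contacts are sorted into five named classes by the one-letter codes of the
two residues (side-chain geometry is deliberately not consulted):

* cation-pi:          positive (R, K, H) with aromatic (F, Y, W)
* electrostatic:      positive (R, K, H) with negative (D, E)
* aromatic:           both aromatic (F, Y, W)
* aliphatic-aromatic: aromatic with aliphatic (G, A, V, L, I, M)
* aliphatic:          both aliphatic

Histidine counts as positive, never as aromatic, so the rule order above is
conflict-free; pairs matching no rule (S, T, N, Q, C, P partners) are typed
``other`` and included in totals but not in the five named classes.

Anchor region 1 (AR1) is the autoinhibitory dock of G/F1 helix V (96-104)
onto J-domain helices II/III (16-56); anchor region 2 (AR2) couples G/F2
residues 118-125 to the J-domain N-terminus (1-28).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .contacts import SubMap, frame_contacts, interdomain_count, persistence_map
from .errors import ContactError, SchemeError
from .model import DomainScheme, Trajectory

__all__ = [
    "AROMATIC",
    "POSITIVE",
    "NEGATIVE",
    "ALIPHATIC",
    "InteractionType",
    "TypeCountSummary",
    "classify_pair",
    "type_counts",
    "anchor_map",
]

AROMATIC = frozenset("FYW")
POSITIVE = frozenset("RKH")
NEGATIVE = frozenset("DE")
ALIPHATIC = frozenset("GAVLIM")

_VALID_CODES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class InteractionType(str, enum.Enum):
    AROMATIC = "aromatic"
    CATION_PI = "cation_pi"
    ELECTROSTATIC = "electrostatic"
    ALIPHATIC = "aliphatic"
    ALIPHATIC_AROMATIC = "aliphatic_aromatic"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify_pair(code_i: str, code_j: str) -> InteractionType:
    """Interaction class of a residue-code pair; symmetric in its arguments."""
    for code in (code_i, code_j):
        if code not in _VALID_CODES:
            raise ContactError(f"unknown one-letter residue code {code!r}")
    a, b = code_i, code_j
    if (a in POSITIVE and b in AROMATIC) or (b in POSITIVE and a in AROMATIC):
        return InteractionType.CATION_PI
    if (a in POSITIVE and b in NEGATIVE) or (b in POSITIVE and a in NEGATIVE):
        return InteractionType.ELECTROSTATIC
    if a in AROMATIC and b in AROMATIC:
        return InteractionType.AROMATIC
    if (a in AROMATIC and b in ALIPHATIC) or (b in AROMATIC and a in ALIPHATIC):
        return InteractionType.ALIPHATIC_AROMATIC
    if a in ALIPHATIC and b in ALIPHATIC:
        return InteractionType.ALIPHATIC
    return InteractionType.OTHER


@dataclass(frozen=True)
class TypeCountSummary:
    """Mean per-frame contact counts between two regions, split by type."""

    regionA: Tuple[int, int]
    regionB: Tuple[int, int]
    mean_counts: Dict[str, float]  # keyed by InteractionType values
    mean_total: float
    n_frames: int

    def named_total(self) -> float:
        """Sum over the five named classes (excludes ``other``)."""
        return sum(
            v
            for k, v in self.mean_counts.items()
            if k != InteractionType.OTHER.value
        )


def type_counts(
    trajectory: Trajectory,
    regionA: Tuple[int, int],
    regionB: Tuple[int, int],
    cutoff: float = 4.0,
    min_separation: int = 4,
) -> TypeCountSummary:
    """Per-type mean number of simultaneous A-B contacts over frames."""
    codes = trajectory[0].residue_code_map()
    totals = {t.value: 0 for t in InteractionType}
    grand = 0
    a1, a2 = regionA
    b1, b2 = regionB
    for frame in trajectory:
        cs = frame_contacts(frame, cutoff=cutoff, min_separation=min_separation)
        for i, j in cs.pairs:
            inter = (a1 <= i <= a2 and b1 <= j <= b2) or (
                b1 <= i <= b2 and a1 <= j <= a2
            )
            if not inter:
                continue
            t = classify_pair(codes[i], codes[j])
            totals[t.value] += 1
            grand += 1
    n = trajectory.n_frames
    return TypeCountSummary(
        regionA=tuple(regionA),
        regionB=tuple(regionB),
        mean_counts={k: v / n for k, v in totals.items()},
        mean_total=grand / n,
        n_frames=n,
    )


_ANCHORS = {
    "AR1": ("helicesII_III", "helixV"),
    "AR2": ("AR2_J", "AR2_GF"),
}


def anchor_regions(anchor: str, scheme: Optional[DomainScheme] = None):
    """The (J-side, G/F-side) residue intervals of an anchor region."""
    scheme = scheme or DomainScheme.default()
    if anchor not in _ANCHORS:
        raise SchemeError(f"unknown anchor {anchor!r}; expected one of {sorted(_ANCHORS)}")
    j_name, gf_name = _ANCHORS[anchor]
    return scheme.region(j_name), scheme.region(gf_name)


def anchor_map(
    trajectory: Trajectory,
    anchor: str,
    scheme: Optional[DomainScheme] = None,
    cutoff: float = 4.0,
    min_separation: int = 4,
) -> SubMap:
    """Persistence sub-map over an anchor's region pair (rows: J side)."""
    j_region, gf_region = anchor_regions(anchor, scheme)
    full = persistence_map(trajectory, cutoff=cutoff, min_separation=min_separation)
    return full.submap(j_region, gf_region)
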