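"""Rule-based closed / open / extended state classification.

The chaperone chain is *closed* when its G/F1 region touches the C-terminal
domain (CTD).  It is *extended* when (1) the CTD touches no part of the G/F
region and (2) fewer than four contacts link G/F2 to the S/T domain.  Every
other frame is *open*.  The two rules cannot both fire: a G/F1-CTD contact
violates the extended condition 1, so each frame receives exactly one label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .contacts import ContactSet, frame_contacts, interdomain_count
from .errors import ContactError
from .model import DomainScheme, Trajectory

__all__ = [
    "StateLabel",
    "StateSeries",
    "TransitionRecord",
    "classify_frame",
    "classify_trajectory",
    "detect_transitions",
    "state_statistics",
]


class StateLabel(str, enum.Enum):
    CLOSED = "closed"
    OPEN = "open"
    EXTENDED = "extended"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class StateSeries:
    """Per-frame state labels, plus the frame-index partition per state."""

    labels: tuple
    frame_interval: Optional[float] = None

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i) -> StateLabel:
        return self.labels[i]

    @property
    def partition(self) -> Dict[StateLabel, List[int]]:
        part: Dict[StateLabel, List[int]] = {s: [] for s in StateLabel}
        for k, lab in enumerate(self.labels):
            part[lab].append(k)
        return part


@dataclass(frozen=True)
class TransitionRecord:
    """A state change at ``frame_index`` (the first frame of the new state)."""

    frame_index: int
    from_state: StateLabel
    to_state: StateLabel

    def __post_init__(self):
        if self.from_state == self.to_state:
            raise ValueError("a transition must change the state")


def classify_frame(
    contacts: ContactSet,
    scheme: DomainScheme,
    extended_threshold: int = 4,
) -> StateLabel:
    """Label one frame from its heavy-atom residue contacts.

    closed   iff >= 1 contact between G/F1 and CTD;
    extended iff no (G/F1 u G/F2)-CTD contact and fewer than
             ``extended_threshold`` G/F2-S/T contacts;
    open     otherwise.
    """
    gf1 = scheme.region("GF1")
    gf2 = scheme.region("GF2")
    st = scheme.region("ST")
    ctd = scheme.region("CTD")
    if interdomain_count(contacts, gf1, ctd) >= 1:
        return StateLabel.CLOSED
    gf_ctd = interdomain_count(contacts, scheme.gf(), ctd)
    gf2_st = interdomain_count(contacts, gf2, st)
    if gf_ctd == 0 and gf2_st < extended_threshold:
        return StateLabel.EXTENDED
    return StateLabel.OPEN


def classify_trajectory(
    trajectory: Trajectory,
    scheme: Optional[DomainScheme] = None,
    cutoff: float = 4.0,
    min_separation: int = 4,
    extended_threshold: int = 4,
) -> StateSeries:
    """Per-frame state labels for a heavy-atom trajectory."""
    scheme = scheme or DomainScheme.default()
    labels = []
    for frame in trajectory:
        cs = frame_contacts(frame, cutoff=cutoff, min_separation=min_separation)
        labels.append(classify_frame(cs, scheme, extended_threshold))
    return StateSeries(labels=tuple(labels), frame_interval=trajectory.frame_interval)


def _majority(labels: Sequence[StateLabel], previous: StateLabel) -> StateLabel:
    counts: Dict[StateLabel, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    top = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == top]
    if len(winners) == 1:
        return winners[0]
    return previous  # tie: keep the previous smoothed label

def detect_transitions(
    series: StateSeries,
    smooth_window: int = 1,
) -> List[TransitionRecord]:
    """State changes of a (optionally majority-smoothed) label series.

    ``smooth_window`` must be odd; 1 disables smoothing.  Smoothing takes a
    centered majority vote (window truncated at the edges); ties keep the
    previous smoothed label.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ContactError(f"smooth_window must be a positive odd integer, got {smooth_window}")
    labels = list(series.labels)
    if smooth_window > 1 and len(labels) > 1:
        half = smooth_window // 2
        smoothed = []
        for t in range(len(labels)):
            lo = max(0, t - half)
            hi = min(len(labels), t + half + 1)
            prev = smoothed[-1] if smoothed else labels[t]
            smoothed.append(_majority(labels[lo:hi], prev))
        labels = smoothed
    out: List[TransitionRecord] = []
    for t in range(1, len(labels)):
        if labels[t] != labels[t - 1]:
            out.append(TransitionRecord(t, labels[t - 1], labels[t]))
    return out


def state_statistics(series: StateSeries, rg_series: Sequence[float]) -> Dict[str, dict]:
    """Per-state frame counts, occupancies and Rg summary statistics.

    ``rg_series`` is the per-frame radius of gyration aligned with the label
    series (any length unit; reported unchanged).  States with zero frames
    get null statistics.  SD is the sample standard deviation (ddof=1),
    undefined (null) for fewer than two frames.
    """
    rg = np.asarray(rg_series, dtype=float)
    if len(rg) != len(series):
        raise ValueError(
            f"rg series length {len(rg)} != state series length {len(series)}"
        )
    out: Dict[str, dict] = {}
    for state in StateLabel:
        idx = series.partition[state]
        entry: dict = {
            "n_frames": len(idx),
            "occupancy": len(idx) / len(series) if len(series) else 0.0,
        }
        if idx:
            vals = rg[idx]
            entry.update(
                rg_mean=float(np.mean(vals)),
                rg_median=float(np.median(vals)),
                rg_sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
            )
        else:
            entry.update(rg_mean=None, rg_median=None, rg_sd=None)
        out[state.value] = entry
    return out
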