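"""End-to-end analysis driver: one trajectory in, a report bundle out.

``run_full_analysis`` reads a (multi-MODEL PDB) trajectory, classifies every
frame, and writes per-state persistence maps, G/F x S/T sub-maps with 1D
contact profiles, the state series with per-state Rg statistics, anchor
region maps with interaction-type summaries, Rg and RMSF tables, and a JSON
summary with the resolved parameters -- all as TSV/JSON, deterministically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import __version__
from .contacts import contact_profile, gf_boundary, persistence_map
from .errors import ContactError, DnajconfError
from .geometry import average_structure, block_average, rg_series, rmsf
from .interactions import anchor_map, anchor_regions, type_counts
from .model import DomainScheme, Trajectory, select_heavy
from .pdbio import read_pdb, write_matrix
from .states import StateLabel, classify_trajectory, detect_transitions, state_statistics

__all__ = ["AnalysisConfig", "run_full_analysis"]

logger = logging.getLogger("dnajconf")


@dataclass
class AnalysisConfig:
    """Resolved parameters of one full-analysis run (serializable)."""

    input_path: str
    output_dir: str
    scheme_path: Optional[str] = None
    chain: Optional[str] = None
    cutoff: float = 4.0
    min_separation: int = 4
    extended_threshold: int = 4
    block_size: int = 1
    smooth_window: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _heavy_trajectory(trajectory: Trajectory) -> Trajectory:
    return Trajectory(
        [select_heavy(f) for f in trajectory], trajectory.frame_interval
    )


def run_full_analysis(config: AnalysisConfig) -> Dict:
    """Run the whole contact/state/anchor/geometry pipeline and write the
    report bundle into ``config.output_dir``.  Returns the summary dict."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = (
        DomainScheme.from_file(config.scheme_path)
        if config.scheme_path
        else DomainScheme.default()
    )
    logger.info("reading trajectory from %s", config.input_path)
    traj = _heavy_trajectory(read_pdb(config.input_path, chain=config.chain))
    kw = dict(cutoff=config.cutoff, min_separation=config.min_separation)

    # --- states ------------------------------------------------------------
    logger.info("classifying %d frames", traj.n_frames)
    series = classify_trajectory(
        traj, scheme, extended_threshold=config.extended_threshold, **kw
    )
    transitions = detect_transitions(series, smooth_window=config.smooth_window)
    rg = rg_series(traj)  # Angstrom
    stats = state_statistics(series, rg)
    with open(outdir / "state_series.tsv", "w") as fh:
        fh.write("frame\tstate\trg_A\trg_nm\n")
        for k, (lab, r) in enumerate(zip(series.labels, rg)):
            fh.write(f"{k}\t{lab.value}\t{r:.6f}\t{r / 10.0:.6f}\n")
    with open(outdir / "transitions.tsv", "w") as fh:
        fh.write("frame\tfrom\tto\n")
        for t in transitions:
            fh.write(f"{t.frame_index}\t{t.from_state.value}\t{t.to_state.value}\n")
    with open(outdir / "state_statistics.json", "w") as fh:
        json.dump(stats, fh, indent=2)

    # --- contact maps, per state ------------------------------------------
    logger.info("building persistence maps")
    write_matrix(persistence_map(traj, **kw), outdir / "persistence_map_all.tsv")
    partition = series.partition
    gf = scheme.gf()
    st = scheme.region("ST")
    for state in StateLabel:
        idx = partition[state]
        if not idx:
            continue
        sub = Trajectory([traj[i] for i in idx])
        pmap = persistence_map(sub, **kw)
        write_matrix(pmap, outdir / f"persistence_map_{state.value}.tsv")
        write_matrix(
            pmap.submap(gf, st), outdir / f"gf_st_submap_{state.value}.tsv"
        )
        write_matrix(
            contact_profile(sub, gf, st, **kw),
            outdir / f"gf_st_profile_{state.value}.tsv",
        )

    # --- G/F boundary ------------------------------------------------------
    profile_vs_J = contact_profile(traj, gf, scheme.region("J"), **kw)
    profile_vs_ST = contact_profile(traj, gf, st, **kw)
    write_matrix(profile_vs_J, outdir / "gf_profile_vs_J.tsv")
    write_matrix(profile_vs_ST, outdir / "gf_profile_vs_ST.tsv")
    try:
        boundary = gf_boundary(profile_vs_J, profile_vs_ST, gf)
    except ContactError:
        boundary = None

    # --- anchor regions ----------------------------------------------------
    anchors: Dict[str, Dict] = {}
    for anchor in ("AR1", "AR2"):
        amap = anchor_map(traj, anchor, scheme, **kw)
        write_matrix(amap, outdir / f"anchor_map_{anchor}.tsv")
        j_region, gf_region = anchor_regions(anchor, scheme)
        summary = type_counts(traj, j_region, gf_region, **kw)
        anchors[anchor] = {
            "mean_total_contacts": summary.mean_total,
            "mean_counts_by_type": summary.mean_counts,
        }

    # --- geometry ----------------------------------------------------------
    logger.info("computing Rg / RMSF")
    with open(outdir / "rg_series.tsv", "w") as fh:
        fh.write("block\trg_A\trg_nm\n")
        for k, v in enumerate(block_average(rg, config.block_size)):
            fh.write(f"{k}\t{v:.6f}\t{v / 10.0:.6f}\n")
    # reference: average structure of the open-state frames when available
    open_idx = partition[StateLabel.OPEN]
    ref_frames = [traj[i] for i in open_idx] if open_idx else traj.frames
    reference = average_structure(Trajectory(ref_frames))
    profile = rmsf(traj, reference)
    with open(outdir / "rmsf.tsv", "w") as fh:
        fh.write("residue\trmsf_A\n")
        for r, v in zip(profile.residues, profile.values):
            fh.write(f"{r}\t{v:.6f}\n")

    # --- summary + provenance ----------------------------------------------
    summary = {
        "software": {"name": "dnajconf", "version": __version__},
        "parameters": asdict(config),
        "scheme": scheme.to_dict(),
        "n_frames": traj.n_frames,
        "state_statistics": stats,
        "n_transitions": len(transitions),
        "gf_boundary": boundary,
        "anchors": anchors,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    config.to_file(outdir / "resolved_config.yaml")
    logger.info("report bundle written to %s", outdir)
    return summary
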