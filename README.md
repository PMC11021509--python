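# dnajconf

Contact-map based conformational-state analysis for multi-domain
Hsp40/J-domain chaperones.

## The problem

DNAJB6b-like J-domain proteins are multi-domain chains — a J-domain
(residues 1–74), a glycine/phenylalanine-rich linker region (G/F, 75–131),
a serine/threonine-rich substrate-binding domain (S/T, 132–188) and a
C-terminal domain (CTD, 189–241) — that interconvert between compact and
extended conformations. Molecular-dynamics studies of such chaperones
characterize the ensemble through residue–residue contact maps: which
domains touch, how persistently, and through which residue chemistries.
Two structural findings dominate that picture: an autoinhibitory *anchor
region 1* (helix V of G/F1, residues 96–104, docked onto J-domain helices
II/III, residues 16–56, burying the Hsp70-activating HPD motif at 31–33)
and a second persistent *anchor region 2* (G/F2 residues 118–125 against
the J-domain N-terminus).

`dnajconf` re-implements that analysis machinery as a reusable, tested
package for anyone working with coordinate trajectories of such proteins:

* **Contacts** — two residues are in contact when any heavy atom of one is
  within 4 Å (inclusive) of any heavy atom of the other; hydrogens are
  excluded, as are sequence neighbours *i*+1…*i*+3. Per-frame contact sets
  aggregate into persistence maps, `P(i,j)` = percent of frames in contact.
* **State classification** — a frame is **closed** iff G/F1 contacts the
  CTD; else **extended** iff the CTD touches no part of G/F *and* fewer
  than four contacts link G/F2 to S/T; else **open**.
* **Interaction typing** — contacts classify by residue identity into
  cation-π (R/K/H with F/Y/W), electrostatic (R/K/H with D/E), aromatic
  (F/Y/W pairs), aliphatic (G/A/V/L/I/M pairs) and aliphatic-aromatic;
  anything else is `other`. Histidine counts as positive, never aromatic.
* **Geometry** — mass-weighted radius of gyration
  R_g = √(Σᵢ mᵢ‖rᵢ − r_com‖² / Σᵢ mᵢ), block averaging, proper-rotation
  Kabsch superposition, iterative average structures, per-residue backbone
  RMSF, and order/disorder fractions from STRIDE-style labels (C/T =
  disordered).
* **Cross-link scoring** — candidate models are ranked against
  lysine-specific XLMS restraints by the fraction of Cα–Cα distances within
  bound (default 30 Å), ties broken by mean violation.
* **Boundary detection** — the split of the G/F region into a J-facing
  G/F1 and an S/T-facing G/F2 is found by maximizing
  Σ_{r<b} profile_vs_J(r) + Σ_{r≥b} profile_vs_ST(r) over split points *b*.
* **Synthetic conformers** — a seeded generator builds 241-residue
  heavy-atom chains whose interdomain contact patterns realize each state
  (and trajectories with prescribed state sequences), so the whole stack is
  testable without an MD engine or downloads.

## Worked example

```bash
dnajconf simulate --sequence closed,open,extended --frames 3 --seed 5 --out traj.pdb
dnajconf full traj.pdb --outdir analysis/
```

`simulate` writes a 9-frame multi-MODEL PDB; `full` then prints a log and
fills `analysis/` with per-state persistence maps, G/F×S/T sub-maps and 1D
profiles, the state series, anchor maps, Rg and RMSF tables, and a
`summary.json` which for this input contains (among other fields):

```
"gf_boundary": 109,
"n_transitions": 2,
"state_statistics": {
  "closed":   {"n_frames": 3, "occupancy": 0.333..., "rg_median": 46.10...},
  "open":     {"n_frames": 3, "occupancy": 0.333..., "rg_median": 47.67...},
  "extended": {"n_frames": 3, "occupancy": 0.333..., "rg_median": 50.81...}
}
```

Each frame was recovered as the state it was generated in (occupancies ⅓
each, two transitions along closed→open→extended), the boundary finder
recovers residue 109 as the G/F split from the 1D contact profiles, and
the Rg medians (Å) order closed < open < extended, the compactness ordering
the classifier's contact rules imply. The anchor summaries in the same file
show the H31–F104 pair at 100% occupancy in all three states — the
autoinhibitory anchor persisting through the conformational cycle.

The same analyses are available per slice (`contacts`, `states`,
`anchors`, `geometry`, `xlms`) and as library functions
(`dnajconf.frame_contacts`, `classify_trajectory`, `anchor_map`, …).

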