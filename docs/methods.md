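# Methods

This note documents the models, conventions and numerical choices behind
`dnajconf`, and what the synthetic test substrate does and does not show.

## Contact model

A residue pair (i, j) is in contact in a frame when the minimum heavy-atom
distance between the residues is ≤ the cutoff. Defaults and conventions:

* **cutoff = 4 Å, inclusive.** The comparison is `d ≤ cutoff`; inclusivity
  is a measure-zero choice on real coordinates but is pinned down so the
  accelerated search and the naive scan agree exactly.
* **Hydrogens are excluded.** `frame_contacts` refuses structures that
  still contain hydrogens rather than silently absorbing them — a hydrogen
  at the interface would effectively inflate the cutoff. Callers apply
  `select_heavy` once at the boundary.
* **min_separation = 4.** Pairs (i, i+1) … (i, i+3) are excluded; the first
  admissible pair is (i, i+4).
* **Persistence** is the percentage of supplied frames containing the pair,
  with all frames weighted equally (no time weighting; frames are assumed
  equally spaced). Persistence maps are symmetric with an identically zero
  |i−j| ≤ 3 band, and are invariant under frame reordering.

The pair search uses `scipy.spatial.cKDTree.query_pairs` (fixed-radius
neighbor query). Its set-equality with a brute-force O(N²) scan is asserted
over random structures in the test suite; there is no approximation.

## State classification

Frames are labelled by interdomain contact counts under a domain scheme
(defaults: J 1–74, G/F1 75–108, G/F2 109–131, S/T 132–188, CTD 189–241):

1. **closed** iff ≥ 1 contact between G/F1 and the CTD;
2. otherwise **extended** iff the CTD has no contact with G/F1 ∪ G/F2 *and*
   the number of G/F2–S/T contacts is < 4 (the `extended_threshold`
   parameter, strict comparison);
3. otherwise **open**.

The two eligibility conditions are mutually exclusive (a G/F1–CTD contact
violates extended condition 1), so the rule is total and unambiguous; this
is property-tested on random contact sets. Near-closed/near-open
intermediate conformations are deliberately *not* classifier outputs: the
three-way rule is the only labelling, and intermediates appear only as
transition context.

Transition detection optionally applies centered majority-vote smoothing
(odd window; ties keep the previous smoothed label; window truncated at the
series edges). The default window is 1 (off): state labels are reported
unsmoothed, and smoothing is an explicit user choice.

## G/F boundary

The split of the G/F region into a J-facing and an S/T-facing half is
formalized as the split point b maximizing

    Σ_{r<b} profile_vs_J(r) + Σ_{r≥b} profile_vs_ST(r),

where the profiles are per-residue mean interdomain contact counts, b
ranges over [gf_start, gf_end + 1], and ties resolve to the smallest b.
Flat-zero profiles are an error ("no boundary signal"); a boundary at the
region start (all J signal C-terminal) is returned with a warning. The
objective is exhaustively scannable, which is exactly how the tests verify
it. On the idealized profile pattern — J contacts confined to 75–108, S/T
contacts to 109–131 — the finder returns 109. The objective is this
package's explicit formalization of a split that is conventionally read
off 1D contact profiles by eye; it is documented as such.

## Interaction typing

Classes are assigned from one-letter residue codes only — backbone- and
side-chain-mediated contacts are typed identically, and no ring geometry is
computed. Rule order: cation-π (positive × aromatic), electrostatic
(positive × negative), aromatic, aliphatic-aromatic, aliphatic, else
`other`. With aromatic = {F, Y, W} excluding histidine, the rules are in
fact conflict-free; the order is retained defensively and the full 210-pair
table is enumerated in the tests. `other` pairs are counted in totals but
not in the five named classes.

## Geometry

* **Masses**: a small element table (H, C, N, O, S, Se, P — standard atomic
  weights). Hydrogen-free input shifts Rg slightly versus all-atom input;
  the caller controls the selection, and the synthetic tests are internally
  consistent (all-heavy).
* **Rg** is mass-weighted and reported in Å with nm alongside (compactness
  of chaperone states is conventionally quoted in nm).
* **Kabsch superposition** uses `scipy.spatial.transform.Rotation.
  align_vectors`, which enforces a proper rotation (det = +1) by sign
  correction of the smallest singular direction; mirror-related inputs keep
  a residual RMSD rather than being reflected. Fewer than 3 selected atoms,
  or a collinear selection, is an error.
* **Average structure**: frames are iteratively superposed onto the running
  mean (backbone selection N, CA, C, O by default) until the mean moves
  < 1e-6 Å (mean per-atom displacement) or 100 iterations, at which point
  the last iterate is returned with a warning.
* **RMSF**: each frame is superposed onto the reference over the selection;
  per-atom RMSF is the RMS deviation from that atom's time-mean position;
  per-residue values are the RMS over the residue's selected atoms (the
  reduction to residue level is a documented package choice). Block
  averaging of series uses non-overlapping blocks with a trailing partial
  block averaged over its actual length; the block size is a frame count,
  not a time, since conversion to time requires an output interval the
  input format does not carry.
* **Disorder**: STRIDE-style letters are consumed, never computed; C and T
  count as disordered, H/G/I/E/B/b as ordered.

## Cross-link scoring

Restraints are Cα–Cα upper bounds (side-chain positions are not assumed
present in candidate models). The default bound, 30 Å, is a conventional
Cα–Cα reach for lysine-reactive cross-linkers; it is configurable per
restraint and prominently so, since the appropriate bound depends on the
reagent. A restraint at exactly its bound counts as satisfied. Ranking is
by descending fraction satisfied, then ascending mean violation among
violated restraints, then input order; the "best fit" criterion is a
documented formalization of a model-selection step whose original criterion
was not spelled out.

## Synthetic conformers

The generator is a geometric fixture, not a physical sampler. Each state
has a deterministic template: short antiparallel "ladder" segments one
contact pitch apart realize the designed residue–residue contacts (AR1:
96–104 against 31–39 including the H31–F104 key pair; AR2: 118–125 against
21–26; G/F2×S/T: 109–114 against 132–137 with a half-step offset so most
residues touch two partners; G/F1×CTD in the closed state: 80–84 against
196–200), while waypoint-routed loops keep every other state-relevant
domain pair far apart. The open template moves the CTD block away from
G/F1; the extended template additionally moves the S/T(+CTD) blocks away
from G/F2. J residues 27–30 dock residue 28 onto G/F1 residue 108 so that
the G/F1 1D contact profile extends to the domain's last residue, as in
the real chain — this is why the boundary finder recovers 109 on generated
trajectories.

Residues carry five heavy atoms (N, CA, C, O and one pseudo side-chain
bead, glycine included); the virtual Cα spacing is 3.8 Å on structured
rows, with connectors allowed to stretch. Conformers are the template plus
seeded Gaussian jitter (0.15 Å for single conformers, 0.2 Å per frame in
trajectories), verified after placement: self-avoiding (min heavy-atom
separation 2.5 Å between residues ≥ 4 apart in sequence, designed contact
pairs exempt — 2.5 Å sits deliberately below the 4 Å cutoff so incidental
contacts remain possible, as in real chains), correctly classified, and
anchor regions present. Failed draws are retried up to 25 times, then an
error suggests relaxing the configuration. Identical config and seed give
bit-identical coordinates.

The default sequence is poly-alanine with functional placements (HPD at
31–33; F at 91/93/100/103/104 and at G/F2 and S/T ladder positions; an
S/T-rich substrate domain with an optional extra-F toggle; ~12 lysines for
cross-link fixtures), so interaction typing and anchor analyses produce a
meaningful class mix without the real (unpublished) sequence.

**What passing tests show, and don't.** The generator proves the analysis
stack end to end — contact detection, classification, typing, anchors,
geometry, scoring — against known ground truth. It does *not* emulate real
chain dimensions (its Rg values, ~4.6–5.1 nm, are larger than a real
241-residue chaperone's 2.1–3.1 nm because the layout is spread flat for
clearance), thermodynamic state populations, realistic transition kinetics,
or secondary structure. Conclusions about real trajectories rest on the
operation contracts, which are format- and scale-independent, not on the
fixture's geometry.

## Problem sizes

Defaults used by the test suite and the acceptance script: trajectories of
9–50 frames of a 241-residue, 1205-heavy-atom chain; 100 random structures
of 100–500 atoms for contact-oracle equivalence; 10,000 random contact
sets for classifier totality; 50 conformers per state for round-trip
fidelity. These sizes exercise every code path while keeping a full run in
well under a minute on one core.

## I/O conventions

PDB v3.3 fixed columns, multi-MODEL for trajectories. Elements come from
columns 77–78 when present, otherwise from the atom name (leading digit →
hydrogen; first alphabetic character otherwise; a two-letter exception list
applies to HETATM names). Alternate locations keep the highest-occupancy
copy (ties: first encountered); insertion codes are rejected; multi-chain
files require an explicit chain selection (the analyses are monomeric).
Coordinates are Å throughout (PDB native). Matrices and profiles are TSV
with residue-index headers, written at six decimals so a round-trip read
reproduces values to 1e-6. Binary trajectory formats (DCD/XTC) are out of
scope: convert with e.g. `mdconvert` or `gmx trjconv` to multi-MODEL PDB.

## Known limitations

* Residue-level contacts only; no atom-level maps, hydrogen-bond or
  salt-bridge geometric criteria.
* Interaction classes ignore side-chain geometry by design.
* No kinetic or free-energy modelling on top of the state series.
* The domain scheme defaults encode residue ranges, not identities;
  sequence-dependent operations take identities from the input file.
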