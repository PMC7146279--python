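# Methods

## The observables

### Lip-center distance and conformational states

The mouth-opening coordinate is the Euclidean distance between the
unweighted geometric centers of the Cα atoms of two lip regions, one on
each subdomain flanking the active-site cleft. Using lip *centers*
rather than minimum inter-lip distances makes the coordinate robust to
individual side-chain or loop excursions.

States are assigned per frame from that distance: closed below
`closed_max` (default 15 Å), open above `open_min` (default 20 Å),
semi-open between. Open and closed are defined by strict inequalities,
so a distance exactly at a threshold is semi-open; this keeps the two
endpoint states conservative and makes the classification total over
all non-negative distances.

A *conversion* is counted each time the state sequence reaches one
endpoint (closed or open) after most recently having been at the other.
Semi-open frames are transparent: they neither count as conversions nor
reset the most recent endpoint. This matches the intuitive reading of
"conversion between the open and closed states" — a trajectory that
only ever wanders between closed and semi-open has zero conversions,
and one full closed→open→closed round trip counts as two.

### Hinge-bending angle

The angle is defined operationally by a two-stage superposition:

1. superpose the frame onto the reference structure by a Kabsch fit of
   the subdomain II Cα atoms common to both (this removes overall
   rigid-body motion, treating subdomain II as the fixed jaw);
2. Kabsch-fit the aligned frame's subdomain I Cα onto the reference's
   subdomain I;
3. report the rotation magnitude `θ = arccos((tr R − 1)/2)` of the
   second fit, clamped into [0°, 180°].

Anchoring on subdomain II mirrors the usual visualization convention
for this family (snapshots superposed on subdomain II). Residues
missing from either structure — crystal gaps are routine — are dropped
from both fits; fewer than three common residues per subdomain is an
error. The reference is user-supplied and defaults to the first
production frame; for crystal-pair comparisons the closed form is the
natural reference. Note the measure is symmetric in frame and
reference, and no attempt is made to localize the hinge axis in space
(DynDom-style axis placement is out of scope).

### Superposition, RMSD, RMSF

Kabsch superposition is computed from the SVD of the cross-covariance
of the centered point sets, with the sign of the smallest singular
vector flipped when needed to force `det R = +1` — reflections are
never returned. Collinear point sets produce a warning but still return
a result. All fits are unweighted: every analysis here operates on Cα
atoms only, where mass weighting would be a constant.

The trajectory RMSD series superposes each frame onto the initial frame
on all Cα atoms and then takes the unfitted paired RMSD over the same
atoms. The fitting selection is a genuine choice — one could instead
anchor on subdomain II as the angle calculation does — and all-Cα
fitting was chosen as the conventional reading of "Cα RMSD"; the
function accepts any fit/analysis selections for users who want the
other convention.

RMSF uses the two-pass mean-structure convention: align every frame to
frame 1 on the alignment selection, average to get a mean structure,
re-align every frame to that mean, and report
`RMSF_i = sqrt(mean_t |x_i(t) − ⟨x_i⟩|²)`. The standard workflow
computes RMSF on production frames only (see pipeline below).

Rotation matrices entering `rotation_angle` are validated as
orthonormal to 1e-6; the arccos argument is clamped to [−1, 1] to
absorb round-off.

### Hydrogen bonds

Detection is purely geometric: donor–acceptor distance ≤ 3.3 Å and the
proton–donor–acceptor angle ≤ 30°, both inclusive. The angle is taken
at the **donor**, between the D→H and D→A vectors, so small values mean
a near-linear D–H···A arrangement; this is the convention of the common
MD post-processing tools, and the phrase "proton-donor-acceptor angle"
is read accordingly. Donors are N/O atoms with a hydrogen within
1.25 Å (proximity rather than CONECT records, which PDB inputs often
lack); acceptors are all N/O atoms. Each unique (donor, hydrogen,
acceptor) triple is reported once per frame; a donor with several
protons can bond one acceptor through each of them.

Crystal structures without protons raise an explicit error rather than
silently returning zero bonds. A documented heavy-atom-only mode
applies the distance criterion alone, marks records with
`hydrogen_index = -1`, and deduplicates unordered heavy-atom pairs
(without protons the donor/acceptor roles are indistinguishable).

Per-frame counts are summarised as mean ± sd with the population
(denominator *T*) convention — the frames of a fixed production window
are treated as the whole population, not a sample. Counting is per
frame, then averaged; pooling conventions that weight bonds by lifetime
are not implemented.

## The synthetic generator

The toy enzyme places two compact residue blocks (Cα only, 3.8 Å
lattice spacing; defaults 100 + 100 residues) on either side of a 9 Å
cleft, offset 25 Å from the hinge point so the hinge has a realistic
lever arm. The mutually closest `lip_fraction` (default 0.25) of each
domain's residues form the lips, numbered so each lip is a contiguous
leading range of its subdomain — the same region semantics as the real
presets. With this geometry the closed mouth sits at 9 Å and crosses
the 20 Å open threshold at θ_open ≈ 19.7°, the same order as the
~16–18° maximal hinge movements reported for ACE-family enzymes. The
generator solves for θ_open from the exact rotated-lip-center geometry
(Rodrigues formula plus Brent root-finding) and rejects geometries that
cannot open by 90°.

Frame *t* rotates domain I rigidly by θ(t) about the hinge axis and
then adds i.i.d. Gaussian noise (default 0.1 Å per coordinate) to
*every* atom, domain II included, so alignment-based analyses face a
noisy anchor as they would in reality. Angle schedules: constant;
sinusoidal (amplitude, period — starts closed); and a Gaussian random
walk with reflecting bounds (default step 1 °/frame in [0°, 30°]),
whose repeated threshold crossings emulate the multiple spontaneous
open↔closed conversions of a ligand-free hinge trajectory. Defaults of
2,000 frames at 0.2 ns/frame span the 400 ns of a typical production
run. All randomness flows through one `numpy` generator seeded
explicitly; identical parameters give bit-identical trajectories.

What the toy does **not** emulate: side chains and their packing,
secondary structure, internal domain flexibility (the domains are
rigid), solvent, and any real energetics — the angle schedule is
imposed, not emergent. Passing tests therefore demonstrate that the
*estimators* are correct (angles, distances, states, conversions, RMSF
are recovered from data with known truth), not that any physical system
behaves this way.

Hydrogen-bond fixtures plant D–H···A triples that satisfy both criteria
with margin (≥ 0.05 Å / 2°) and decoys that violate exactly one
criterion by at least the same margin, alternating which, on a 20 Å
grid so no cross-triple bond can form. Donor-side atoms and acceptors
are placed in opposite selections, and a pair of inert carbons keeps
selections non-empty in degenerate cases.

## Pipeline conventions

* Equilibration is trimmed by **time** (ns), keeping frames strictly
  after the cutoff, since published equilibration intervals are quoted
  in ns.
* The RMSD series is computed on the **full** trajectory (its purpose
  is to show departure from the starting structure, including the
  equilibration transient); hinge statistics, RMSF and hydrogen-bond
  summaries use production frames only.
* Multi-model PDB and topology-plus-coordinate-stream inputs are
  supported; when the input carries no times, frame times default to
  frame index × a user-supplied timestep. Automatic equilibration
  detection is deliberately not attempted — the cutoff is an input.
* Alternate locations resolve to the highest-occupancy copy, ties to
  the alphabetically earlier altloc. Residue ranges are author (PDB)
  numbering, inclusive on both ends. Residues declared in a region but
  absent from a structure are reported and skipped, not fatal.
* HETATM records are kept and flagged; Cα selections exclude them by
  construction (a calcium ion named CA can never enter a lip).
* Reports echo the full configuration, package version and input
  checksums; every summary is recomputable from the per-frame tables it
  accompanies.

## Region presets

The sACE C-domain preset carries the lip I/II and subdomain I/II
residue ranges in 4APH author numbering. The ACE2 preset's lips are the
published sequence-correspondence ranges (1R4L/1R42 numbering); ACE2
subdomain boundaries are not published alongside them, so the preset
ships an approximate contiguous partition analogous to the sACE layout,
adequate for anchoring the hinge-angle superposition and documented as
approximate in the file. A known numbering discrepancy: one published
figure caption lists the "second lip" with the ACE2 residue numbers
while the text defines the sACE lip II as 128–150, 160–173, 284–293;
the sACE preset follows the text definition, and the discrepancy is
noted here rather than resolved.

## Problem sizes and tolerances

Validation runs use the default 200-residue toy with 2,000-frame
trajectories — large enough for stable statistics (the RMSF χ-form
check at T = 2,000 has per-residue sampling error under 1 %) while
keeping the full suite around a minute and a half. Hinge-angle recovery
is exact to < 1e-6° noise-free and accurate to ≈ 0.3–0.4° mean absolute
error at 0.3 Å coordinate noise, comfortably inside the 1.5° bound the
tests assert. Kabsch recovery of constructed motions is checked to
1e-9 Å RMSD over 1,000 random motions, and geometric H-bond detection
is required to agree *exactly* with a brute-force all-pairs oracle.

## Known limitations

* The hinge angle reports rotation magnitude only; axis position and
  orientation, and any translation component along the axis, are not
  analyzed.
* Lip distances use Cα centers; analyses based on solvent-accessible
  mouth width or cleft volume would need different machinery.
* Hydrogen-bond detection has no energetic component and no
  water-mediated-bridge detection; salt bridges and hydrophobic
  contacts are out of scope.
* The PDB reader handles ATOM/HETATM/MODEL records; mmCIF is not
  parsed, and bond topology is never perceived.
* State populations are occupancies, not free energies; no kinetic or
  Markov modelling is attempted.
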