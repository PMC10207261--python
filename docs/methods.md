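# Methods

## What the package models

`tmbundle` analyzes trajectories of seven-transmembrane (7TM) receptor
bundles to decide whether a predicted structure keeps its fold under
dynamics. The analysis stages — mutual-RMSD model comparison with an MDS
projection, per-replica stability descriptors, water-permeation counting,
gromos conformational clustering and contact-map interface comparison —
are generic; the defaults are tuned to the class A GPCR / olfactory
receptor setting: an inactive-state receptor in a 100 × 100 × 120 Å
periodic box, membrane normal along z, with the conserved sodium pocket
formed by the acidic side chains at Ballesteros–Weinstein positions 2.50
and 3.39.

Units throughout: ångström for coordinates and distances, nanoseconds for
time. Residue numbering is taken verbatim from the source PDB and never
renumbered; all position-generic logic is anchored through a
user-supplied residue → BW-label table (two-column TSV). BW labels are
never inferred from sequence motifs — motif conservation in olfactory
receptors is too weak for that to be safe.

## Superposition and RMSD

Kabsch superposition is implemented once, as the SVD closed form with the
determinant sign correction that excludes reflections, and shared by all
callers. Collinear point sets are rejected (the rotation about the line
is undetermined). `rmsd_fitted` separates the fitting selection from the
measurement selection so that, e.g., a trajectory can be fitted on the TM
backbone while the RMSD is reported over all heavy atoms. The mutual
matrix fits every pair independently (no global reference), which is the
convention expected by gromos clustering; the O(n²) cost is acceptable
because clustering operates on strided frames (default: every 10th) —
the stride is a config parameter, and the default study produces 180
strided frames from 18 replicas.

Which atoms define "backbone RMSD" is genuinely ambiguous in the
literature; here backbone = N, CA, C, O (CA-only is available as a
selection class). Model comparison defaults to the whole-chain backbone
— comparing predictions is about the entire fold, loops included —
whereas clustering defaults to TM-only heavy atoms, because loops are the
least reliable part of both predictions and simulations. Both choices
are configurable.

## Classical MDS

Torgerson MDS (double-center −½·J·D²·J, eigendecompose, scale
eigenvectors by √λ) rather than iterative SMACOF: it is deterministic,
exact for distance matrices embeddable in the target dimension, and
entirely adequate for visualizing a handful of models. RMSD matrices need
not be Euclidean, so negative eigenvalues are clamped to zero with a
logged warning. The sign ambiguity of eigenvectors is canonicalized by
making the first off-origin point non-negative on every axis; reported
`stress` is the relative residual √(Σ(d−δ)²/Σδ²). Note that the
canonical *coordinates* depend on which item is listed first; only the
embedded distances are permutation-equivariant.

## Stability descriptors

**RMSD series** — one value per frame against a fixed reference (by
default the input predictor model rather than frame 0, so that early
relaxation away from the prediction is visible). The summary statistic is
the mean over the trailing 20 % of frames ("final-window mean").

**TM6–TM7 spacing** — the published closed/open ranges (7–9 Å closed,
13–15 Å open) do not come with a measurement definition, so two are
provided. The default, `axis_midplane`, fits each helix axis per frame
and measures the distance between the two axes evaluated at the membrane
midplane (box z-center); this matches the geometry of the splaying motion
that separates the cytoplasmic interface. `ca_com` (distance between Cα
centroids of the cytoplasmic halves) is the simpler alternative. Helix
axes are estimated by the bisector construction: for consecutive point
triples, cross products of successive chord bisectors are exactly
parallel to the axis of an ideal helix regardless of its twist; the axis
anchor point is the least-squares circle center of the points projected
perpendicular to that direction. A principal-component line is the
fallback for straight/degenerate input. For strongly bent helices any
straight-axis definition is approximate; on smoothly deformed synthetic
bundles the residual disagreement between the scripted centroid
separation and the measured axis-midplane distance grows to roughly 0.5 Å
per ångström of planted backbone deformation amplitude — one reason the
study scenarios keep model divergence in the realistic 0.5–6 Å range.

**Activation index** — implemented as a configurable linear functional
`intercept + Σ coeff · d(Cαᵢ, Cαⱼ)` over BW-addressed residue pairs. The
published A¹⁰⁰ coefficient set belongs to its original authors'
supporting material and is deliberately **not** hardcoded; an editable
YAML template ships with the CLI (`tmbundle a100-template`). The
convention is that values below a user-chosen threshold indicate
inactive-like conformations.

**Sodium-site occupancy** — a frame is occupied iff any selected ion is
within the contact cutoff (default 3.0 Å, a typical Na⁺–carboxylate
coordination distance) of any carboxylate oxygen (OD1/OD2/OE1/OE2) of the
residues at positions 2.50 and 3.39. Distances use the minimum-image
convention for orthorhombic boxes; the protein is assumed whole (not
wrapped). Occupancy is the occupied-frame fraction; the first binding
time is the time stamp of the first occupied frame.

## Permeation counting

The box is partitioned along z into intracellular (IC, below the slab),
extracellular (EC, above it) and the membrane slab; inside the slab,
positions within a cylinder around the bundle are TM ("through the
receptor") and the rest is BULK. Defaults: slab = ±20 Å about the box
z-center, cylinder radius 12 Å around the per-frame TM-Cα centroid. A
permeation event is a maximal IC→(TM…)→EC passage (or the reverse) of one
water oxygen that visits TM at least once and never touches BULK between
leaving one compartment and reaching the other — waters that go around
the protein are not counted; hydrogens are ignored. `entry_frame` is the
last frame in the origin compartment, `exit_frame` the first in the
destination.

Counting full crossings (rather than any interior flooding) is a
deliberate operationalization choice; it makes counts well-defined,
time-reversal symmetric (reversing the trajectory swaps the direction
labels exactly) and stable under frame-rate refinement.

Periodic wraps need no special handling in the state machine: a wrap
teleports a particle between deep IC and deep EC without visiting the
slab, so the through-TM requirement already discards it. The `unwrap_z`
utility (successive differences folded into ±box/2) is provided for
continuous single-particle tracks; it assumes frame-to-frame motion
smaller than half the box, which holds for physical sampling rates.

## gromos clustering and contacts

The gromos procedure: among unassigned items, the one with the most
unassigned neighbors within the cutoff becomes a cluster centroid; it and
its neighbors are removed; repeat. Ties on neighbor count are broken by
the lowest item index, making the output deterministic. Clusters are
renumbered 1-based by decreasing population. The default cutoff is 2.5 Å
on TM heavy atoms. The per-source membership table (model × cluster
counts, with per-cluster source purity) is how "do two predictors sample
the same basin?" is answered.

Contact maps record residue pairs of a helix pair whose minimum
heavy-atom distance is ≤ 4.5 Å, computed on single structures (cluster
centroids), not trajectory averages. The cutoff is a conventional
heavy-atom contact criterion — the web tools used for such maps rarely
print theirs — and is recorded in every output. Interface comparison is
set algebra on the per-helix residue sets; MSA conservation counts treat
gaps as "not allowed" and require the anchor column of every requested BW
position to be given explicitly.

## The synthetic generator

`synthetic.make_bundle` builds an idealized poly-alanine 7-helix bundle:
ideal α-helix geometry (1.5 Å rise, 100° twist per residue), backbone
N/CA/C/O plus CB, helices on a circle of radius 11 Å (adjacent axes
~9.5 Å apart) running antiparallel along z inside the 100 × 100 × 120 Å
box, joined by short loop residues. Every helix residue gets a BW label
`h.(50+offset)` with the midpoint at h.50. The residues at 2.50 and 3.39
are relabelled ASP/GLU and given pseudo-carboxylate oxygens that converge
on a single pocket point between helices 2 and 3 — as the real acidic
pair does around a bound sodium — so the pocket-midpoint ion position is
within ~1.8 Å of an oxygen.

`make_trajectory` is purely kinematic: a splay schedule rigidly displaces
the named helix pair along the line joining their axes so the scripted
axis-distance ramp is met exactly; scripted waters are single-oxygen
residues following piecewise-linear z-paths wrapped into the box
(variants: genuine crossings, crossings routed through a forced periodic
wrap, bounce-backs, around-the-protein paths, bulk wrap drifts); the
sodium ion toggles between a bulk parking position and the
carboxylate-oxygen midpoint; Gaussian noise of `noise_sigma` (default
0.2 Å in the study, a modest thermal-jitter stand-in) is added to every
atom. Everything is driven by one seeded RNG; outputs are bit-identical
for a fixed seed.

`make_model_set` plants exact mutual backbone RMSDs: variant *i* adds
`xᵢ·u + yᵢ·w` to the backbone, where (xᵢ, yᵢ) are planted 2D coordinates
and u, w are unit-RMSD fields built from smooth low-frequency amplitude
profiles along two fixed perpendicular directions. The profiles are
projected to have zero net translation and zero net torque and to be
mutually orthogonal; this keeps the cross-covariance of any two variants
symmetric positive definite, so the optimal Kabsch rotation is exactly
the identity and every pairwise RMSD equals the planted Euclidean
distance — the planted configuration is exactly 2D-embeddable by
construction. Smoothness matters: it deforms helices gently (bending, not
shattering), which is both closer to how predictor models actually differ
and necessary for helix-axis metrics to remain meaningful. Non-backbone
atoms follow their residue's CA displacement.

What the generator does **not** emulate: lipids (the slab is purely
geometric), thermodynamics and force fields, side chains beyond CB,
correlated thermal motion, diffusive water paths, and spontaneous —
rather than scripted — ion binding. Passing recovery tests therefore
demonstrates the correctness of the *measurement* machinery under known
ground truth (including PBC bookkeeping and decoy rejection), not the
physical realism of any simulation.

## The study design and verdict rule

The default mini-study is 6 models × 3 replicas × 100 frames at 5 ns per
frame (500 ns per replica): three sodium-bound stable models (two of
them 0.5 Å apart, sharing a basin; all pinned at the 8 Å closed TM6–TM7
spacing), one sodium-bound model with two planted permeations, and two
sodium-free models that splay 8 → 14 Å with three permeations each.
Planted model coordinates keep all distinct basins ≥ ~2.7 Å apart —
beyond the 2.5 Å cluster cutoff. Pinning the spacing in non-splaying
scenarios is part of the script: it prevents model-to-model fold
divergence from masquerading as a TM6–TM7 opening.

Verdicts are a pure function of recorded metrics and thresholds, so every
report is recomputable from its JSON alone: `fold_broken` iff the maximum
TM6–TM7 spacing ≥ 12 Å (the midpoint between the closed 7–9 Å and open
13–15 Å ranges); else `water_leak` iff ≥ 1 complete permeation; else
`stable`. The qualitative published classifications carry no numeric
rule; this is an explicit, documented operationalization, and both
thresholds are config values logged into every report.

## Numerical choices and degenerate inputs

- Orthorhombic boxes only; triclinic input is rejected with a clear error.
- Hydrogens are `element == "H"`; the element is inferred from the first
  alphabetic character of the atom name when the PDB element column is
  absent (with a small ion-name table for NA/CL/…).
- PDB coordinates are quantized to 0.001 Å (the format's precision);
  round-trips through the plain-text `frames` trajectory dialect are
  exact at full float precision.
- Degenerate superposition inputs (n < 3, collinear) raise; empty
  selections raise rather than returning empty results.
- The gromos tie-break (lowest index) and size-ordered 1-based cluster
  ids make clustering bit-reproducible.
- All-zero distance matrices embed to the origin with zero stress.

## Known limitations

- Atom correspondence between models is positional; there is no
  sequence-alignment fallback for comparing different proteins.
- The axis-midplane TM spacing is a straight-axis approximation; for
  strongly kinked helices the `ca_com` mode is the more robust choice.
- The permeation detector requires waters to be resolvable per frame; it
  does not attempt identity tracking across wrap-induced index changes
  (identities are stable in both supported trajectory dialects).
- Binary MD trajectory formats are out of scope for the core; the
  documented plain-text dialect and multi-model PDB are the supported
  interchange formats, and adapters can convert externally.
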