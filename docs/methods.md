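# Methods

This note records the models and procedures memsurf implements, the
conventions and defaults it adopts where the underlying analyses admit more
than one reading, and what its synthetic fixtures do and do not emulate.

## Units and numbering

All internal geometry is in ångström and nanoseconds; angles in degrees.
GRO files (nm) are converted at the I/O boundary, and contact maps are
reported in nm — the customary scale for residue-contact maps — with the
conversion applied once at the map boundary. Residues are numbered
globally, 1-based and continuously across chains (a 42+42 dimer spans
1..84); chain-local numbering is a derived view. The PDB dialect follows
wwPDB v3.3 columns with one extension: the residue-name field spans
columns 18–21 so four-letter lipid names (POPC) survive a round trip.
Insertion codes and altlocs are rejected rather than silently dropped.

## Minimum-image distances

For an orthorhombic box, the per-axis nearest-image reduction
d → d − L·round(d/L) minimizes each squared component independently, so it
equals the exact minimum over all 27 periodic images for any input
coordinates (wrapped or not). The test suite asserts this equality against
the explicit 27-image enumeration on seeded random systems. The same
kernel, restricted to x–y with periodicity in two axes, drives the lateral
annular criterion.

## Attachment-time detection

The protein–lipid minimum-distance trace of a binding event shows a sharp,
roughly linear decline followed by a stabilized plateau. The attachment
time is defined graphically: fit a least-squares line to the decline, a
horizontal line (the mean) to the plateau, and intersect them. memsurf
realizes this as an exhaustive grid search over interior breakpoints k:
the line is fitted to samples 0..k and the plateau mean to samples k..end
(sample k shared, pinning both fits to the transition); the k minimizing
the total squared error wins, with ties broken toward the earliest k. The
search is O(n) per breakpoint via prefix sums, fully deterministic, and
equivariant under time shifts. A fit whose optimal decline slope is not
negative raises a no-attachment error, as does a globally flat trace or
fewer than 8 samples.

`plateau_fraction` (default 0.25) sets the minimum fraction of samples the
plateau segment must retain, bounding how late the breakpoint may sit.
Analyses of traces whose plateau is known to occupy less than a quarter of
the observation window should lower it (the recovery tests covering
breakpoints up to 90% of the trace use 0.05); the default favours
robustness on noisy traces where a late spurious breakpoint could swallow
the plateau.

With a noiseless piecewise-linear trace whose kink falls on a sample, the
two-segment fit is exact and the intersection reproduces the kink to
machine precision; off-grid kinks are recovered to within one sample
interval because exactly one sample is shared between regimes.

## Secondary structure

The assigner follows the Kabsch–Sander dictionary. Backbone amide
hydrogens are placed geometrically — 1.0 Å from N along the reversed
carbonyl direction of the preceding residue, none on prolines or
chain-initial residues — matching the convention of reference
implementations for structures without explicit hydrogens. Donor→acceptor
pairs within 9 Å (CA–CA prescreen) are scored with
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol and bonded when
E < −0.5; sub-0.5-Å contacts raise a clash error rather than returning a
huge energy.

From the bond pattern: n-turns (i→i+n, n = 3, 4, 5) within one chain;
helices G/H/I from two consecutive n-turns (residues i..i+n−1); parallel
and antiparallel bridges from the standard two-bond patterns between
sequence-non-adjacent residues (inter-chain pairs allowed — that is what
pairs the dimer's strands); ladders from consecutive bridges, giving E,
with isolated bridges left as B; turn T for interior residues of any
n-turn; bend S where the CA(i−2)→CA(i)→CA(i+2) direction changes by more
than 70°. Priority on conflicts: H > B/E > G > I > T > S > coil. Residues
with incomplete backbones are coded C with a warning.

The matrix view adds a ninth code: one all-X separator row between
consecutive chains (residue index 0), mirroring how per-residue
structure-vs-time matrices of multi-chain proteins are conventionally
plotted. Reduced hydrogen-bonded classes are BE = {B, E},
GHI = {G, H, I}, T = {T}; S, C and X are non-hydrogen-bonded and enter no
reduced class, so BEGHIT = BE + GHI + T holds identically. Counts are
aggregated per N-/C-terminal domain across chains.

On ideal fixtures the assigner matches mdtraj's DSSP implementation
residue-for-residue (the test threshold is 90% to leave room for termini
conventions).

## Contact maps and zones

A contact-map entry (i, j) is the minimum inter-atomic distance between
residues i and j under the minimum image, using heavy atoms only by
default — fixtures may carry placed amide hydrogens, and including them
would bias the minima; a flag includes all atoms. Averaging is two-stage:
per replicate the arithmetic mean over frames in the trailing window
(default 50 ns), then the unweighted mean across replicates. A
single-frame replicate is accepted as a degenerate window; a multi-frame
replicate spanning less than the window raises an error naming it.

The zone directory enumerates the 10 unordered pairings of the four
domains of a two-chain dimer: within-chain A (N_A/N_A, N_A/C_A, C_A/C_A →
zones 1–3), within-chain B (→ 4–6), inter-chain (N_A/N_B, N_A/C_B,
C_A/N_B, C_A/C_B → 7–10). Zone means use strict i < j residue pairs within
a domain (the diagonal zeros would deflate within-domain means) and the
full cross-product between distinct domains; with this convention the
union of all zones covers exactly R(R−1)/2 pairs. Cross-replicate spread
is reported as SEM = sd/√n with the n−1 denominator; with a single
replicate the SEM is NaN — explicitly not available, never zero.

## Annular sorting

A lipid or water molecule is annular when any of its atoms comes within
the cutoff of any protein atom, whole molecules assigned atomically. The
default criterion is lateral (x–y projected, periodic in x and y),
matching the top-down view of an annular shell around a surface-bound
protein; a 3D criterion is one flag away. The default cutoff of 6 Å
approximates the first lipid coordination shell and is a documented
tunable, not a measured constant. Labels are monotone in the cutoff and,
in lateral mode, invariant under rigid z-translations.

## Leaflet asymmetry

The bilayer midplane is the mean z of all headgroup atoms (robust to
bilayers not centred in the box); a lipid is upper iff its headgroup lies
above it, and a headgroup exactly on the midplane is an error rather than
a silent coin-flip. Both mismatch percentages are symmetric, bounded in
[0, 100], zero iff their arguments are equal, and scale-invariant. Per-
leaflet areas default to the shared lateral box area, under which the two
percentages coincide to machine precision; externally estimated
per-leaflet areas (e.g. Voronoi-based) are accepted as inputs but never
computed here.

## Synthetic fixtures

The generators are pure functions of their spec including the seed
(byte-identical output across runs), with no global RNG state.

*Bilayers* are 3-atom caricatures: one "P" headgroup exactly on the
±leaflet_sep/2 plane (default separation 38 Å, about a phosphate-to-
phosphate distance of a fluid PC bilayer) on a laterally jittered square
grid, two tail beads toward the midplane. Both leaflets share a lateral
box of area max(n_upper, n_lower)·apl with apl defaulting to 65 Å², a
typical fluid-phase PC area per lipid. Only leaflet topology, counts and
the headgroup planes matter to the analyses; conformational realism is
explicitly not emulated, so passing tests say nothing about lipid
conformational statistics.

*Binding trajectories* translate a rigid extended-backbone dimer toward
the upper leaflet so its lowest atom sits exactly
d(t) = max(plateau, d0 − rate·t) above the headgroup plane, laterally
aligned with one headgroup; rate = (d0 − plateau)/t_attach. Noise is a
Gaussian jitter on the whole-protein z-offset, not per-atom, so the
noiseless measured minimum distance equals the prescribed curve to
machine precision — the property that makes exact parameter-recovery
tests possible. Defaults (d0 = 50 Å, plateau = 2.5 Å, t_end = 60 ns,
dt = 0.1 ns) represent a protein released a few nanometres above the
membrane and settling into headgroup contact. The box height is chosen so
z minimum images never wrap. What the fixture does not emulate: protein
conformational change during binding, lipid response, or any force field —
recovery tests validate the estimator, not binding physics.

*Ideal geometries* build backbones by internal-coordinate (NeRF) chain
extension at ideal bond lengths (N–CA 1.458, CA–C 1.525, C–N 1.329,
C=O 1.231 Å) and uniform dihedrals: α-helix (−57°, −47°), β-strand
(−139°, 135°), extended (180°, 180°) for the dimer builder, chains offset
laterally by 10 Å. The antiparallel β-pair applies the two-fold symmetry
of an ideal sheet — strand B is strand A rotated 180° about the pairing
axis and offset 4.8 Å along it — with a fixed registry shift of −1.9 Å
along the strand axis, determined once so that the two hydrogen bonds of
each bridge form simultaneously at ~2.9 Å N···O without backbone clashes
and frozen as a constant.

## Problem sizes in tests

The suites run at desk scale by design: random point sets of 50×80 atoms
for the distance oracle (100 seeds), 10-residue frames for contact-map
brute-force equality (50 seeds), 50 noiseless plus 20 noisy traces of 601
samples for attachment recovery, 1000 random columns for the reduced-class
identity, and bilayers of tens to hundreds of lipids. These sizes exercise
every code path; the algorithms are O(N·M) per frame in selection sizes
and scale to full MD systems linearly in frames.

## Known limitations

* Binary trajectory formats (XTC/TRR/DCD) are out of scope; multi-model
  PDB and GRO cover the text-format scale this package targets.
* The assigner implements the core Kabsch–Sander rules without the bulge
  extension of ladders; on idealized fixtures this is exact, on irregular
  sheets it can fragment E runs where a reference implementation bridges
  them.
* The Surround-style annular criterion here (lateral/3D cutoff,
  whole-molecule) is the simplest reading consistent with shell renderings
  of bound proteins; the original algorithm's exact criterion is not
  published in a form that could be matched, so mode and cutoff are
  config-exposed stand-ins.
* The orientation angle keeps the full [0, 180]° range rather than
  folding to [0, 90]°; callers wanting the folded convention can apply
  min(θ, 180 − θ).
* Attachment plateaus near zero distance interact with the non-negativity
  of distances: heavy noise folds at zero and biases the plateau estimate
  slightly upward. At the noise levels tested (1.4 Å on a 2.5 Å plateau)
  the induced attachment-time error is well under one sample interval on
  average.
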