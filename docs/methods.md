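# Methods

## The problem

Subtomogram averaging aligns and averages many noisy cubic subvolumes
cut from cryo-electron tomograms.  When the object of interest sits in
a crowded neighborhood — the canonical case here is a small protein
density sandwiched between two lipid bilayers at a vesicle–vesicle
contact — the surrounding membranes carry far more signal than the
object.  Classification and refinement then lock onto the membranes,
and because membrane geometry varies from particle to particle
(vesicle diameter and curvature are not conserved), the object of
interest is dragged along and smeared out of the average.  This
package implements the two ideas that address this:

1. **Feature-guided alignment** — initialize each particle's
   orientation from a picked coordinate pair (an interface point and a
   second point identifying which side the vesicle of interest is on),
   removing the polarity ambiguity of the pseudo-symmetric two-membrane
   geometry before any reference-based search runs.
2. **Focused 3D signal permutation** — randomize the positions of the
   voxel values outside a per-particle mask so that the background
   becomes featureless while the global voxel statistics of the
   subtomogram are exactly preserved, with a distance-graded schedule
   that blurs rather than cuts the mask boundary, plus an optional
   intensity-outlier filter.

Everything else (3D classification, refinement, post-processing) is
deliberately left to the external refinement package; this library
prepares its inputs and consumes its outputs through RELION-dialect
STAR tables and MRC2014 volumes.

## Conventions

* Volumes are cubic, addressed `data[x, y, z]`, box center at voxel
  `floor(N/2)` per axis, pixel size in Å.  MRC I/O and STAR parsing go
  through gemmi; unknown STAR columns round-trip untouched.
* Orientations are ZYZ intrinsic Euler angles `(rot, tilt, psi)` in
  degrees with `A = Rz(psi)·Ry(tilt)·Rz(rot)`.  `A` maps reference
  directions into the particle frame: the picked feature direction is
  `v = A·ez`, so it is carried by `(tilt, psi)` alone and `rot` is the
  free spin about `v`.  Feature-guided assignment therefore computes
  `(tilt, psi)` from the Rodrigues rotation taking `+z` onto `v`
  (axis `r = a×v/|a×v|`, angle `θ = acos(a·v/|a||v|)` with
  `a = [0,0,1]`), draws `rot` uniformly from a single seeded generator
  consumed in record order, and copies `tilt/psi` into the prior
  columns for the downstream restrained search.
* The defining, tested contract: applying the inverse of the stored
  rotation to `v` yields `+z` to 1e-9.  Tie-breaks: antiparallel `v`
  uses axis `[1,0,0]`; when `tilt < 1e-6°` the in-plane angle folds
  into `psi` and `rot = 0`.
* A reference-frame mask reaches particle `i` through the inverse
  alignment, `M_rot_trans = R⁻¹M − T`; with the storage convention
  above that is `transform_mask(M, (Aᵀ, origin))`.  Masks are resampled
  trilinearly on the {0,1} field and re-binarized at 0.5 — smoother
  boundaries than nearest-neighbor while keeping a binary contract.

## Signal permutation

Given a placed mask, the outside of the box is partitioned into
concentric pseudo-shells by thresholding the Euclidean distance
transform at multiples of `step` (isotropic shells, not cubic
dilation).  Shell `k` contributes each voxel to the permutation pool
independently with probability `f_k`; everything beyond the last shell
joins outright.  The pooled values are permuted jointly as one
population (a per-shell-local variant exists behind a flag).  Because a
permutation only moves values, the multiset of voxel values — hence
mean and standard deviation — is conserved exactly, and voxels inside
the mask are bit-identical to the input.

The fraction schedule is a user parameter with default linear ramp
`f_k = k/(n_shells+1)` (default `step = 2`, `n_shells = 5`): the
simplest monotone family realizing "more randomization farther from
the mask".  The outlier filter replaces outside-mask voxels beyond
`mean + w·SD` or below `mean − b·SD` (defaults `w = b = 3`, statistics
of the input volume computed once) with draws from Normal(m, s),
default (0, 1) for a z-scored subtomogram.  Filtering runs after
permutation.  Per-particle randomness derives from
`SeedSequence([global_seed, record_index])`, so results are independent
of batch partitioning and byte-reproducible.

## Missing wedge and constrained correlation

A single-axis tilt scheme over `[tilt_min, tilt_max]` samples, in the
plane perpendicular to the tilt axis, only the directions whose angle
from the untilted in-plane axis lies in that range; the binary wedge
volume encodes this with DC at the box center, hard-edged, and exactly
symmetric under point inversion (including the Nyquist planes of an
even box, which are explicitly symmetrized — relevant for rotated
wedges).  Note the expected fill fraction (e.g. 2/3 for ±60°) holds
over the inscribed Nyquist ball; over the full cube the corner
directions are overweighted and the fraction is higher (~0.711 for
±60°), a property of cubes rather than of the wedge.

Cross-correlation against a class average imposes the wedge on the
average only (the subtomogram already carries the experimental wedge)
and computes a Pearson coefficient over a region mask after aligning
the particle into the average's frame; a centered cube is the default
region shape.  Pruning keeps records with `ccc ≥ threshold` and
annotates every record.

The Wiener visualization filter is `C/(C² + 1/SSNR)` with the standard
phase-contrast CTF `C = √(1−A²)·sin χ + A·cos χ`,
`χ = πλzf² − (π/2)Cs λ³f⁴` (defocus taken as underfocus by magnitude),
and `SSNR(f) = snr0·exp(−5·falloff·f/f_Nyquist)`.  The SSNR decay
constant is a package choice: at `falloff = 1.2` the top third of the
spectrum loses most of its power, which is the intended visualization
behavior; no bit-parity with any other implementation is claimed.

## QC analytics

Midsection averaging takes the mean of the central `thickness` planes
(default 21, odd by contract) perpendicular to a chosen axis; the
center trace averages the central `width` columns per row.  Bilayer
metrics find the two largest local maxima in a search window with a
local minimum between them; peak magnitude is the mean of the maxima
minus that minimum, and half-height widths are measured per peak at
half the peak height above a baseline taken as the trace mean outside
the window (the baseline choice is a package decision and is recorded
per run).  Flat or monotone traces return "no double peak" rather than
raising.  The flip diagnostic rotates each particle's unit feature
vector by the inverse of its stored alignment and classifies by the
sign of the z-component (`z = 0` counts as top and is reported); it is
exactly invariant to adding any global `rot` offset.

## Synthetic phantoms

The generator renders two opposed bilayers perpendicular to z — each
leaflet a Gaussian sheet, giving the double-peaked trace signature —
plus an intermembrane density (cylinder, bar, or blob), at defaults of
a 64³ box, 5.24 Å/voxel, leaflet peaks 8 voxels (42 Å ≈ 4 nm) apart and
bilayer midplanes 24 voxels (126 Å) apart: a desk-scale vesicle contact
with membranes a little thinner than physiological so that two of them
plus a gap fit the box.  Particles are the reference under known random
rigid transforms (tilt uniform on the sphere, `rot/psi` uniform, small
uniform shifts), plus Gaussian noise of SD 2 relative to unit signal
amplitude, filtered by a ±60° wedge, then z-scored.  Noise is added
before wedge filtering so the noise carries the wedge as in real data.
The truth table stores the exact angles/offsets, and the pair file
stores coordinates consistent with the applied rotation, so
feature-guided assignment of the truth pairs yields a flip fraction of
exactly 0.  A forced-flip option rotates the *stored* orientation of a
chosen fraction of records by 180° about x to construct mixtures with
an exact flip fraction.

What the phantom does **not** emulate: CTF modulation, per-tilt dose
and drift, molecular-detail densities, tomogram-scale context with
neighboring objects, or non-Gaussian (structured) background.  Passing
tests therefore demonstrate the correctness of the geometry,
conservation laws, and the background-suppression mechanism — not
resolution claims on real data.

## The background-recovery experiment

`background_recovery_experiment` is the desk-scale analogue of the
method's payoff, designed around the one mechanism that makes
background permutation matter: the membranes are *decoupled* from the
density of interest.  Each of 50 particles shows the interface at a
true tilt `β ~ U(±20°)` about y (offset to a sideways pose, where a
single-axis tilt scheme actually samples bilayers), but its membranes
are additionally tilted by a private `δ ~ U(±18°)` — emulating
vesicle curvature/diameter variability.  Each particle is processed
raw and signal-permuted outside a focused cylinder placed with the
true transform (full permutation of all outside voxels: the membranes
graze the mask boundary here, so no graded blur; 3-SD outlier filter).
A 1-D orientation search over tilt candidates (step 2.5°, offset half
a step so no candidate is an exact lattice rotation, which would skip
interpolation smoothing and bias scores) scores a centered cube
against the reference filtered by the candidate-rotated wedge.  On raw
particles the membranes dominate the score and drag the optimum toward
`β+δ` (mean |error| ≈ 8°); on permuted particles the background is
featureless and the bar-shaped density fixes the optimum near `β`
(mean |error| ≈ 3.5°).  The averages built from the recovered
orientations are compared to the clean reference inside the focused
mask; the permuted branch wins strictly on every tested seed.

Taking the literal alternative — averaging both branches with the
*true* transforms — is provably a tie: permutation leaves in-mask
voxels bit-identical and identical transforms map the mask onto
itself, so the orientation search is an essential part of the
experiment, as it is of the real workflow.

## Numerical choices and problem sizes

* Resampling: `scipy.ndimage.affine_transform`, trilinear, constant
  fill 0; masks re-binarized at 0.5.
* Shells: `scipy.ndimage.distance_transform_edt` distances to mask
  voxel centers; shell populations run ~15% below continuum thin-shell
  estimates because of the half-voxel center bias — tests check against
  an exact KD-tree brute-force oracle instead.
* Statistical tests average over 20 seeds with 4-SD binomial bands;
  geometry round-trips check 500 random rotations against a
  scipy quaternion oracle at 1e-9.
* Default test and acceptance problem sizes: 64³ boxes, 50 particles,
  5 seeds for the recovery experiment — sizes at which every stage of
  the pipeline is exercised end-to-end on one CPU in minutes.

## Known limitations

* The wedge is binary with a hard edge; the optional raised-cosine
  edge is off by default.  Dose weighting and per-tilt 3D-CTF
  correction are out of scope (they belong to reconstruction).
* The orientation search in the recovery experiment is 1-D by design;
  it demonstrates the mechanism, it is not a refinement engine.
* Data-derived masks are supported only as user-binarized imports; no
  automatic mask generation recipe is provided.
* `tilt` priors assume the RELION-style restrained local search
  downstream; the package does not itself restrain anything.
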