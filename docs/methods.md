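# Methods

This note records the geometric conventions, calibrations and design
choices behind `helixbend`, in the order the pipeline applies them.

## Data model

A *conformation* is one all-atom duplex model: exactly two chains of equal
length, contiguous 1-based residue numbering, A/U/G/C residues carrying at
least C1', the glycosidic nitrogen and the base ring atoms.  Strand II is
stored 5'→3' in its own chain; the antiparallel in-register pairing
(residue *i* of strand I with residue *N*+1−*i* of strand II) is resolved
by `infer_pairing`, never by file order.  Pairs are Watson–Crick when the
residue combination is AU/UA/GC/CG/GU/UG, otherwise mismatches; contiguous
mismatch runs flanked by WC pairs on both sides are internal loops.
Hydrogens are accepted on input and ignored — every criterion in the
package is heavy-atom only.

## The synthetic generator

The generator replaces MD sampling with geometric ground truth.  Its
defaults are the study conditions used throughout the tests.

**Ideal builds.**  Base-pair frames of an ideal duplex lie exactly on the
global helix axis, consecutive frames related by the fiber screw (twist
32.0°, rise 2.81 Å by default — the standard relaxed A-form values the
analysis is anchored to).  Strand-I bases sit at the standard reference
frame coordinates; WC partners are generated by negating y and z of their
own template.  Because the frames are on-axis and uninclined, the
frame/step pipeline recovers (twist, rise) to 1e-6 with all other step
parameters zero — the exactness every round-trip test builds on.  The
`FiberParameters` fields `x_displacement`/`inclination` exist for
generating non-ideal placements but default to zero; the A-form character
of the build (deep, narrow major groove) is carried entirely by the
backbone template below.

**Backbone template.**  No experimental structures are bundled; the
sugar/phosphate stub attached to each base was designed once by least
squares over nine atom positions (O4', C2', O2', C3', O3', C4', C5', O5',
P in a C1'-anchored local frame shared by all four bases) against:
standard ribose bond lengths and valence angles; an anti glycosidic
torsion (χ ≈ −159°); the inter-residue O3'(i)–P(i+1) closure of the
32°/2.81 Å helix; a steric floor of 2.9 Å against neighboring residues;
a phosphate-radius prior of ~9.5 Å; and the groove anchor described next.
The resulting coordinates are frozen in `templates.SUGAR_LOCAL`;
`scripts/design_backbone_template.py` reproduces the derivation.

**Perturbations.**  A *bend* is a circular arc: equal hinge rotations
about one fixed lab axis perpendicular to the initial helix axis, applied
at every interior step, base pairs moving rigidly.  (A constant per-step
*roll* increment would instead wind a superhelix, because the roll axis
co-rotates with the helical twist; the fixed-axis form is what makes the
end-to-end axis direction change equal the imposed angle.)  The default
terminal margin keeps 12 steps at each end straight — terminal exclusion
(5) plus the bending estimator's 7-step end windows — so the imposed angle
is exactly the quantity the estimator measures; for duplexes shorter than
~28 bp the margin shrinks to keep at least one hinge.  A *kink* is a
single rigid hinge: all pairs beyond the kink step rotate about an axis
through the mid-step origin perpendicular to the local helix axis.
*Overextension* rebuilds the helical placement at overridden
(twist ≤ 32°, rise ≥ 2.81 Å) with base-pair internal geometry unchanged.
*Groove modulation* scales phosphate positions radially about the local
axis per step.  Ensembles draw per-model bends uniformly from
[bend_min, bend_total] with uniform random bend-plane azimuth, apply the
kink and overrides as given, add isotropic Gaussian coordinate noise last,
and return a ground-truth manifest; everything derives from one
`numpy.random.default_rng(seed)`.

**Mismatch geometries.**  Non-canonical positions (and the standalone
two-residue pair builder) embed placements found by the hydrogen-bond
search below: by default the maximum-bond ("canonical") geometry of the
pair type, or any requested achievable bond count.  Among grid placements
with the requested count, the one closest to the WC partner position is
chosen, keeping the duplex embedding tidy and the choice deterministic.

## Frames and step parameters

Base frames are least-squares (SVD) rigid superpositions of the
standard-frame ring-atom template onto the observed ring atoms (exocyclic
substituents excluded for robustness to propeller/buckle); the fit RMSD is
reported.  The pair frame flips the strand-II frame (y, z negated) and
averages by the half-rotation construction; pairs whose flipped z-axes
still oppose strand I by more than 90° are flagged "flipped" and excluded
from step statistics.  Step parameters use the mid-step-frame algorithm:
the bend angle Γ between the two z-axes is removed symmetrically about the
hinge axis z₁×z₂; twist is the signed angle between the unbent x-axes
about the mean z; Γ splits into roll/tilt by its phase against the
mid-frame y-axis; the origin displacement expressed in the mid-frame gives
shift/slide/rise.  One convention is implemented and documented; different
published tools differ from it (and from each other) by tenths of degrees.
χ is the O4'–C1'–N1–C2 (pyrimidine) / O4'–C1'–N9–C4 (purine) torsion,
classified anti for χ ∈ (−180°, −90°) ∪ (150°, 180°], syn for (0°, 90°),
otherwise reported as intermediate.

## Groove widths and collapse

Each strand's phosphorus atoms form a polyline over residue index, boxcar-
smoothed over 3 nodes (the "refined" trace) and linearly interpolated at
0.1-step resolution.  For step *s* the major (minor) groove width is the
minimal distance between the strand-I polyline within ±0.5 of the step
midpoint and the strand-II polyline within ±1.5 of a fixed cross-strand
offset: in summed-index units j = x + u − N − 1, the windows sit at the
two branch minima of the ideal build, j = −4.47 (major) and +4.02
(minor).  Steps whose window runs off the helix end are undefined (NaN)
and excluded from all means and counts — never imputed.  No van-der-Waals
subtraction is applied by default (`subtract` option available).

Two printed anchors constrain the one free calibration: a perfect A-form
helix has Mgw ≈ 12 Å, and *collapse* means Mgw noticeably decreased below
~12 Å — so the relaxed form itself is, by definition, not collapsed.
Calibrating the ideal build to exactly 12.0 Å would place it *at* the
collapse threshold, where symmetric fluctuations mark half of a straight
helix collapsed and destroy the monotone collapse–bend relationship the
convention exists to expose.  The template is therefore calibrated so the
measured ideal value is 12.2 Å: equal to the printed anchor at its stated
precision ("around 12 Å"), and strictly above the 12 Å threshold.  With
this convention, collapse counts are zero for the clean ideal helix,
grow monotonically with imposed bend, and rank-correlate with the bending
angle at ρ ≈ 0.65 across noisy bent ensembles (σ = 0.3 Å, 200 models).

## Axis, bending, kink, θ

The curvilinear axis is the polyline of per-step screw decompositions of
consecutive pair frames: rotation axis (oriented along the mean z),
foot point nearest the step midpoint; near-zero-rotation steps inherit the
nearest defined direction.  Raw per-step points/directions are stored and
boxcar-smoothed over 5 steps on access.  Terminal exclusion (default 5
pairs per end) slices the *raw* arrays before smoothing, so excluded pairs
have exactly zero influence on any retained quantity.

The global bending angle is the angle between the mean axis directions
over the first and last end windows of the retained region; the end means
average window + smoothing − 1 = 7 raw directions (the raw support of a
3-step window of smoothed vectors), truncated to at most half the region.
At σ = 0.3 Å noise this estimator has a zero-bend floor of ≈ 4.4° MAE and
recovers imposed 20–60° bends to ≈ 2.5° MAE.  Bent-state categories:
moderately (< 40°), strongly (40–50°), extremely (> 50°) bent.

Kink analysis fits one line and the best two-segment partition (minimum
segment length 4) to the axis points.  A kink is reported when the
two-segment fit reduces the residual by ≥ 40 %, the single-line RMS
residual exceeds a 0.5 Å noise floor, and both segments are individually
straight (RMS ≤ 1.0 Å) — the last condition implements the bent/kinked
distinction: a continuously curved axis also gains from two segments, but
its halves stay curved.  The kink angle is the angle between the segment
directions oriented along the chain; imposed 50–90° hinges at σ = 0.3 Å
are recovered to < 1° MAE with the split located within ±2 steps.  All
three thresholds are keyword-configurable.

θ uses the unweighted heavy-atom centroid of each base pair ("center of
mass" is ambiguous with respect to weighting and hydrogens; the unweighted
heavy-atom reading is the simplest reproducible one): v_i joins
consecutive centroids and θ_i is the angle between v_i and v_{i+1}.  For
an ideal helix θ matches the closed-form chord angle
arccos((c²·cosΩ + h²)/(c² + h²)), c = 2·r·sin(Ω/2), exactly.

## Hydrogen bonds

Criteria (heavy-atom only, configurable): donor–acceptor distance
≤ 3.5 Å and, for every bonded heavy neighbor of the donor, an
antecedent–donor–acceptor angle ≥ 110° as a proxy for the proton pointing
at the acceptor.  Donors/acceptors follow base chemistry (A: N6 / N1, N3,
N7; G: N1, N2 / O6, N3, N7; C: N4 / O2, N3; U: N3 / O2, O4) with O2' as
both.  Matching is greedy by ascending distance, each atom in at most one
bond, ties broken lexically — deterministic, and immune to bifurcated
double counting.  Closing WC pairs are *distorted* when they hold fewer
than their canonical count (AU 2, GC 3, GU 2).

The maximum-simultaneous-bond search enumerates coplanar anti/anti
placements of the flipped partner base on a rigid grid (5° rotation,
0.2 Å translation along a C1'–C1' annulus), constrained to duplex
embedding: C1'–C1' distance 8.8–11.2 Å (bracketing the WC span at 10.4 Å,
the narrowed ~9.2 Å span of pyrimidine–pyrimidine pairs, and slightly
widened purine–purine placements) and both glycosidic vectors at 20–80°
to the C1'–C1' line; placements with any non-bonded cross-pair contact
below 2.5 Å are rejected.  Only base atoms participate (the sugar
conformation is not resolved at the level of a planar base placement).
Under this search: GC 3, AU 2, GU 2, UU 2, CC 1, CU 2, AA 1 — the WC
sanity values, the two-bond UU/CU states, the single-bond ceiling of
neutral C·C, and an A·A purine pair capped at one bond, consistent with
the 0/1-bond A·A states seen in CAG-repeat ensembles.  Pair-state counts
reported by the classifier are capped at the pair type's maximum.

Loop pooling keeps every internal loop except the first and last; when a
construct has exactly two loops, both are kept.  For loop-conformation
clustering each retained loop is augmented with its strand-swapped
symmetric copy.

## Ensemble statistics

Models are superposed to the first model (all heavy atoms, least squares)
before featurization, making clustering invariant to rigid motion of the
ensemble.  k-means (fixed seed, 10 restarts) runs on flattened
coordinates; when k is not fixed, a silhouette sweep over 8–20 (clipped to
n − 1) selects it.  Cluster average structures are coordinate means after
superposition to the cluster medoid.  The bending table sums cluster
populations into left-closed bins 0–20/20–30/30–40/40–50/50–60/>60° with
the population-weighted mean angle; on generated ensembles the measured
bin fractions match the imposed-bend distribution within binomial error at
200 models.  2D histograms are probability-mass normalized; Mgw is paired
with θ, mgw, twist, slide and shift per (model, step).

## What the generator does and does not emulate

Generated ensembles have exactly controlled global deformations,
idealized mismatch geometries and isotropic Gaussian coordinate noise.
They do not emulate thermal backbone torsional dynamics, sequence-
dependent fiber parameters, base-pair opening/fraying, solvent or ions,
or the correlated local–global couplings of real trajectories.  Passing
recovery tests therefore demonstrates that the measurement pipeline is
accurate and unbiased on known ground truth at realistic noise levels —
not that any particular biological ensemble bends by a given amount, and
trajectory-derived population percentages are out of reach by design.
Problem sizes used in the test suite — 24–64 bp duplexes, 200-model
ensembles — were chosen as the smallest at which the estimators' noise
floors and the binomial tolerances of the recovery comparisons are
comfortably resolved.

## Numerical notes and limitations

* PDB-bound coordinates are float32 at 0.001 Å precision; generated
  structures carry float64 coordinates alongside so exact round trips are
  not storage-limited.
* Step decomposition is undefined for antiparallel pair z-axes; such pairs
  are flagged and excluded rather than forced.
* The groove convention reports NaN where the cross-strand window leaves
  the helix; profiles of duplexes shorter than ~8 bp are entirely
  undefined.
* Kink position is localized to ±2 steps; axis smoothing smears hinges
  over the smoothing window, and shallow smooth bends (≲ 25°) can satisfy
  the two-segment criterion and be reported as small-angle kinks — kink
  calls are meaningful alongside the bending magnitude.
* The placement search grid (5°, 0.2 Å) is coarse; it is an existence
  search for bond-count maxima, not an energy minimizer, and its
  geometries are idealized starting structures, not predictions.
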