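# Methods

`flashmap` implements the analysis chain used to follow a photoswitchable
ligand leaving its binding pocket in a time-resolved serial
crystallography experiment: isomorphous difference maps over a series of
pump-probe delays, Pearson-correlation segmentation of the timeline into
kinetic regimes, an apo-normalized ligand-release curve, structure-factor
extrapolation with estimation of the photoactivation level, and backbone
displacement fields.  Everything is exercised end to end on a seeded
synthetic two-state toy crystal whose ground truth is known.

## Crystallographic core

Structure factors use a flat (point-atom) scattering model: each element
contributes its electron count Z damped by an isotropic Debye-Waller
factor, F(h) = sum_j occ_j Z_j exp(-B_j s^2/4) exp(2 pi i h.x_j) with
s = 1/d.  This omits the 4/5-Gaussian form-factor parameterisations of
production crystallography; for synthetic verification it has the
advantage of being exactly invertible, and every downstream operation
(differences, extrapolation, integrals) is linear in F and insensitive
to the form-factor shape.  All computation is in P1; merged amplitudes
from higher-symmetry groups are accepted and treated as an expanded P1
set with a warning, since the difference arithmetic is symmetry-agnostic.

Maps are synthesized by FFT from one reflection per Friedel pair with
automatic conjugate completion; F(000) is always excluded, so maps are
zero-mean by construction.  The default grid is the smallest even shape
giving a spacing of at most dmin/3 per axis (the sampling used for map
display is not standardized; dmin/3 is our choice).  Sigma scaling
divides a zero-mean map by its rms; "3 sigma" thresholds are in this
unit.

## Difference maps and scaling

Light amplitudes are scaled onto dark with an isotropic model
log(F_dark/F_light) = log k - B s^2/4 fitted by least squares over
reflections common to both sets, with amplitudes weaker than 2 sigma
discarded in **both** sets (the stricter, symmetric reading) and the
resolution restricted to 6-1.7 Å by default.  An optional
per-resolution-shell residual scale is available for real data and off
by default.  Difference maps use coefficients
(F_light - F_dark) exp(i phi_dark) with phases from the refined dark
model; reflections missing on either side are dropped, never imputed,
and no difference weighting is applied by default (a weighting hook
exists).

### A common sigma unit across a series

For a series of delay maps (and during activation scans, below) all maps
are placed on **one** density scale - the sigma unit of a reference map
(the strongest delay map for the timeline; the largest-A map for a
scan) - instead of rescaling each map by its own rms.  In real data the
two conventions coincide to about a percent, because the map rms is
dominated by merging noise and the enormous static structure, both of
which barely change between delays.  In a 38-atom toy cell they do not:
per-map rescaling divides out exactly the growth of the features being
measured (an over-subtracted ligand atom grows linearly with the
extrapolation multiplier, but so does the map rms, cancelling the
signal).  The common-scale convention restores the behaviour the method
relies on in the regime it was designed for.  Pearson correlations are
unaffected (they are invariant to per-map scale); the release curve and
activation scans depend on it.

## Density metrics

Signed density is integrated in spheres around selected atoms with
periodic minimum-image distances; each voxel counts once and is assigned
to its nearest selected atom.  Values weaker than the sigma threshold
(1.5 sigma for correlation vectors, 3 sigma for release/activation
integrals) are ignored, and negative-density integrals are reported as
positive magnitudes.  The per-atom signed integrals over all protein
atoms (waters and hydrogens excluded) form the observation vector whose
delay-vs-delay Pearson matrix, normalized to its largest entry, is the
timeline fingerprint; entries below 0.3 are flagged as omitted for
display but kept in the data.  Block structure is read off by a greedy
contiguous segmentation: a delay joins the current block while its
normalized correlation with every member stays at or above the display
threshold.

Pattern-count equalization mimics subsampling every delay to the
worst-sampled one: noise is inflated by sqrt(count/min_count) per delay
(the sqrt-N merging law), so correlations are not biased by
multiplicity.

The release curve integrates negative density around all ligand atoms
(1.5 Å, 3 sigma) per delay and for the apo-minus-dark map.  The apo
value is first multiplied by 1/sqrt(occupancy_ratio) (0.5 for the
default fourfold ratio, treating an occupancy advantage like a
multiplicity advantage in signal-to-noise), then the curve is normalized
so that the smallest delay value is 0 and the rescaled apo value is 1.
If rescaled apo does not exceed every delay value, the normalization is
flagged degenerate and raw magnitudes are still returned.

## Extrapolation and the activation level

F_extra = (100/A)(F_light - F_dark) + F_calc per common index; entries
with non-positive extrapolated amplitude are removed before synthesis
(removal never alters surviving amplitudes), and
sigma_extra = (100/A) sqrt(sigma_light^2 + sigma_dark^2) treats F_calc
as noiseless.  Maps use 2F_extra - F_calc coefficients with dark-model
phases: with model phases a difference feature appears at roughly half
height and the doubled difference restores it, so at the correct A the
map shows the activated state with no residual at departed-ligand atoms.

The activation level is scanned from A = 100% down to 5% in 1% steps
(configurable).  Negative density around the ligand nitrogens (which
leave their dark pose in every photoproduct state) stays near zero while
A is above the truth and grows once the dark state is over-subtracted;
the control estimator instead integrates positive density at the same
dark-only positions, which vanishes at and below the truth.  Both curves
are piecewise **linear in the multiplier m = 100/A** (the
over-subtracted or residual occupancy is m a - 1, resp. 1 - m a), and
hyperbolic in A; the breakpoint is therefore fitted in m.  The fit is a
continuous broken-stick (segmented) least-squares regression - two lines
constrained to meet at a free knot, the knot searched exhaustively over
the scanned abscissae and midpoints - followed by refitting each side as
a free line and intersecting them.  We first implemented the literal
discontinuous variant (independent lines per side, split chosen by total
SSE) and found it unstable: on curves with a convex tail the SSE optimum
splits inside the tail, and intersections of near-parallel lines can
land anywhere.  The broken-stick knot pins the regime change; the final
intersection realizes "the intersection of the linear parts".  A
constant curve raises a no-breakpoint error; for the re-appearance
control a constant curve (full conversion) reports the scan boundary.

Per-delay estimates are reported individually along with their mean,
mirroring how a spread of per-delay values (here 14-24% for a true 22%)
is averaged into a single refinement value.  Early,
metastable-block delays give the most accurate single-delay estimates -
the displaced pose is well defined - and are what the acceptance checks
use; late delays inherit the extra signature of pocket relaxation and
scatter more, which the pipeline simply reports.

## Backbone displacement fields

Pseudo-Calpha atoms are matched by (chain, residue number); the vector
is state B minus state A in cartesian space.  A vector is shown when its
magnitude reaches the 0.5 Å significance cutoff and its residue ordinal
falls on the display stride (every second residue); drawn arrows are six
times the true length.  No superposition is applied by default (states
from one crystal form share a frame); an optional least-squares
superposition on matched Calphas is provided.  Alternate conformers are
dropped on reading.

## Thermodynamics

ddG = dG_bound - dG_unbound for the cis-to-trans gap in the two
environments (+5 kcal/mol with the study inputs -14 and -19 kcal/mol),
and the equilibrium affinity fold-change is exp(ddG/RT).  The
temperature behind the printed fold-change is not stated; 300 K (the
simulation target temperature) reproduces the ~4300x figure within ~2%
and is the default, exposed as an argument.

## The synthetic toy crystal

A 20 x 24 x 28 Å P1 cell contains 30 pseudo-protein "residues", each a
single calcium-like scatterer (Z = 20, B ~ 28-32 Å^2) standing in for
several light atoms - this keeps the moving ligand a small fraction of
the total scattering and the light-dark phase changes small, as in a
real protein crystal - and an 8-atom ligand (B ~ 5 Å^2, well ordered)
whose "A-ring" half carries the two reporter nitrogens.  Ten protein
atoms form a pocket shell around the ligand; data extend to 1.55 Å.
States: metastable (A-ring rigidly relocated by 2.5 Å, echoing the
~2.6 Å ring relocation scale of the relaxed pose), open (the A-ring in a
second, distinct pose plus a five-atom gate opening of 0.8-2.2 Å), and
apo (ligand absent, gate back at its dark position, three other shell
atoms relaxed by 0.9-1.2 Å).  Poses are rejection-sampled so relocated
rings never overlap old-pose or pocket atoms; the three difference
signatures are therefore nearly orthogonal, which is what produces three
clean correlation blocks.

Per delay, complex structure factors of the states are population-mixed:
F_mix = sum_s p_s F_s with the dark fraction always 1 - A/100 (default
A = 22%).  Observed amplitudes are | |F_mix| + eps | with
eps ~ N(0, (0.02 |F_mix| sqrt(n_ref/n_delay))^2), seeded; the sigmaF
column records the truth.  Pattern counts are uneven across the nine
delays (minimum 55,065, the worst-sampled delay of the study design);
the dark and apo sets have higher multiplicity (apo about fourfold the
worst delay).  Because mixing is done on complex structure factors, the
pipeline's linear amplitude approximation is genuinely tested, bias
included (about 9% relative rms on extrapolated amplitudes at A = 22).

Two population modes exist.  The crisp default assigns the whole
activated fraction to one state per block (delays 1-3 metastable, 4-6
open, 7-9 apo) - the reference three-block scenario used for block
recovery and activation tests.  The smooth mode advances the activated
population with stretched-exponential progress curves
(apo: beta = 0.12, tau = 0.1 ms, near log-uniform over the nine decades;
open: beta = 0.6, tau = 0.6 us), giving a strictly monotone decline of
old-pose ligand occupancy with a resolvable step at every delay - the
scenario for release-curve fidelity checks.

### What the toy does and does not emulate

It reproduces: mixed-population amplitudes with a dark floor, sqrt-N
merging noise and uneven multiplicities, paired difference peaks from
sub-Å motions, the three-regime timeline, occupancy-limited extrapolation
with negative-amplitude removal, and an apo dataset on a different
occupancy footing.  It does not emulate: space-group symmetry and
systematic absences, anisotropy, radiation damage, per-image scaling,
solvent (bulk or ordered), form-factor shapes, or refinement feedback.
Passing tests therefore validate the arithmetic and the estimators under
the statistical structure the analysis assumes, not the upstream data
reduction of a real experiment.

## Numerical choices and degenerate inputs

- Joins between reflection sets are exact on (h,k,l); missing indices
  are dropped everywhere, never imputed.
- Sigma scaling of a constant map raises; an identical light/dark pair
  is reported as a "null difference".
- Zero-variance per-atom vectors make a correlation undefined: the
  entry is NaN, marked missing, and excluded from display.
- The breakpoint fit requires at least two points per segment and
  raises on parallel (featureless) segments; estimates are clamped to
  the scanned range and flagged when at a boundary.
- All randomness flows from a single integer seed per scenario;
  every pipeline product is byte-reproducible for fixed inputs.

## Problem sizes

Default runs use ~7,500 unique reflections (dmin 1.55 Å in the toy
cell), a 40 x 48 x 56 map grid, nine delays, and a 96-point activation
scan per delay; a full timeline completes in well under a minute on one
CPU, and the test suite uses coarser activation grids where the scan
itself is not under test.
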