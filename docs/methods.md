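# Methods

`epijam` quantifies collective dynamics of crowding epithelial monolayers:
how much cells move (V_rms), how far their motion is coordinated (the
velocity correlation length ξ_v), how often they exchange neighbors (the T1
rate R_T1), how their shapes change (aspect ratio and shape index q), and
when transitions happen in time (sigmoidal marker fits, change-point
detection of the motility decline). The package pairs every estimator with
a synthetic generator that produces the same kind of data with exact ground
truth, so each stage is validated end to end without external imaging data.

## Kinematics

**PIV.** Velocity fields are estimated by single-pass FFT cross-correlation
of interrogation windows (default 32 px, 50% overlap). The correlation
surface is normalized by the lag-dependent overlap count, which removes the
bias toward zero lag inherent to zero-padded correlation; the peak is
refined with a three-point Gaussian fit per axis (parabolic fallback when a
neighbor is non-positive). A window is accepted only if the
primary-to-secondary peak ratio is ≥ 1.2 (secondary peak searched outside a
3-px exclusion zone) *and* the normalized correlation at the peak is ≥
0.25; the second gate rejects windows that match nothing (e.g. pure noise),
which the ratio test alone cannot do reliably because the correlation
surface is locally smooth. On textured phantoms with a known uniform shift
the median error is ≈ 0.04 px and ≥ 95% of windows land within 0.2 px.
Pixel arrays are y-down; displacements are flipped to y-up physical
coordinates (µm, h) at this boundary.

**V_rms.** The bare spatial root mean square of the velocity field,
V_rms = √⟨|v|²⟩. Whether the study of record removed mean drift before
averaging is not stated in its methods, so both the bare and the
mean-subtracted variants are always co-reported and a flag selects which
one downstream consumers read. On generated data the two coincide because
the generators impose no net drift.

**Velocity correlation and ξ_v.** C(r) is the radially averaged
⟨δv(x)·δv(x+r)⟩/⟨|δv|²⟩ with δv the per-field mean-subtracted velocity,
accumulated over all ordered node pairs including self-pairs (so the
zero-distance bin is exactly 1). ξ_v is the linearly interpolated first
crossing of C(r) = 1/e — a parameter-free estimator that is standard in
collective-migration work; a `no_crossing` status is returned when C stays
above 1/e within r_max, and `insufficient_data` when fluctuations vanish
(uniform field) or too many bins are empty. The binned accumulation is
checked against an all-pairs brute-force sum to 1e-10. Validation fields
with an exactly imposed exponential correlation are produced by circulant
embedding on the periodic grid; the estimator recovers an imposed 40 µm
length with ≈ −5% median bias, attributable to mean subtraction over a
finite (480 µm) domain.

**Strain rates.** The velocity gradient is fitted node-wise by least
squares over a 3×3 neighborhood (≥ 6 valid nodes required; exact for affine
fields). With E the symmetric part, the isotropic rate is tr(E)/2 and the
deviatoric magnitude is the Frobenius norm of the traceless part; a
max-shear convention (largest eigenvalue of the traceless part) is
available by flag. Affine test fields reconstruct both invariants to
< 1e-10.

## Topology

**Neighbor graphs.** From label masks, two cells are adjacent iff their
4-connected shared boundary is at least ε_edge = 0.05 × the mean equivalent
cell diameter, which removes four-fold-vertex ambiguity (corner contacts
have zero shared length and never count). From centroids, adjacency comes
from the Voronoi tessellation (periodic by 3×3 tiling, or bounded with
hull-touching cells flagged) with the same ε_edge rule on ridge lengths.
Cells on the image border or convex hull are flagged and excluded from rate
denominators and shape statistics.

**T1 detection.** A T1 is the collapse of the junction between two adjacent
cells followed by a new junction between two previously non-adjacent cells.
Between consecutive frames, a lost edge (A,B) and a gained edge (C,D) form
an event iff the four cells are distinct, the four side edges A–C, A–D,
B–C, B–D exist in both frames (this makes detection exactly symmetric under
time reversal and matches the geometry of a genuine junction exchange), the
old junction was stable for k frames and the new one persists for k frames
(default k = 2, suppressing segmentation flicker). Rosettes are decomposed
greedily by lost-junction length, ties broken by lowest canonical id pair.
Each event is reported once, at the first frame containing the new
junction. The detector is verified to agree exactly with a brute-force
adjacency-difference oracle on random graph sequences.

**Rates and shapes.** R_T1 is events per interior cell per hour in
half-open time bins. The shape index is reported as the dimensionless
q = P/√A (the standard jamming-literature quantity, lower bound 2√π for a
disk); the literal perimeter/area ratio is co-reported because printed
descriptions sometimes use that form. Aspect ratio is the axis ratio of the
second-moment ellipse, computed analytically for polygons and via
`regionprops` (Crofton perimeter) for masks. The speed comparison contrasts
central-difference speeds of event quartets at completion with topological
neighbors that participate in no event within ± window frames, using a
two-sided Wilcoxon rank-sum test.

## Jamming analysis

**Rigid-pack null model.** If rearrangements are confined to interfaces
between coherent packs of size L_c, the interface cell fraction scales as
f_int ~ 1/L_c ~ 1/V_rms while the relative speed of neighboring packs
scales as V_rel ~ V_rms, so R_T1 ~ f_int·V_rel is independent of V_rms. The
scaling carries no absolute constants, so the prediction is operationalized
with one calibration pair (V_rms*, R_T1*): the predicted rate equals R_T1*
at every V_rms, and the testable content is constancy versus linearity of
R_T1(V_rms).

**Rate–speed inference.** The slope of R_T1 on V_rms is estimated by OLS
on time-binned pairs. Because bin rates are Poisson-like and
heteroscedastic, the CI uses a symmetric studentized pairs bootstrap
(slopes studentized by a heteroscedasticity-robust SE; measured coverage
94–96% at n ≈ 30 pairs). The p-value for slope = 0 uses a seeded
permutation of rates against speeds: a plain percentile-bootstrap p-value
measured 8.4% type-I error at nominal 5% in this regime, whereas the
permutation test is exact under the no-association null (measured 5.8% over
500 null simulations). Defaults: 2000 resamples, explicit integer seed.

**Sigmoid fits.** Marker transitions are fitted with a four-parameter
logistic on a log10 time axis, y = bottom + (top−bottom)/(1+(EC50/t)^hill),
by multi-start seeded least squares (data-driven bottom/top/EC50 starts, a
ladder of hill slopes, jittered restarts). The fitted location parameter is
logEC50 = log10 EC50 and EC50 is reported in hours, matching the convention
of curve-fitting software that labels the midpoint parameter "LogEC50" even
when the X axis is time; on this axis the fit is exactly equivariant to
time *scaling* (logEC50 shifts by log10 s) and to value scaling. Noiseless
15-point series are recovered to 1e-6; at 5% noise the median EC50 error is
≈ 1.3 h.

**Onset detection.** The motility-decline onset is the breakpoint of a
continuous two-segment piecewise-linear fit, grid-searched over interior
sample times, with a seeded residual-bootstrap CI. Flat series and edge
fits are flagged rather than reported as onsets. The estimator is invariant
to adding a constant.

## Synthetic data

The generators are kinematic stand-ins with controlled statistics, not
mechanical (vertex/SPV) models: they impose speeds, correlations, and
exchange rates directly so that downstream estimates can be compared with
exact ground truth.

* **Defaults as study conditions.** 500 µm periodic box, 400 cells, 15-min
  frame interval (dt = 0.25 h), up to 144 h — the geometry and cadence of a
  long-term epithelial crowding time-lapse. Field size and cell count are
  fixture choices (not reported quantities); centroid jitter defaults to
  0.1 µm, a sub-pixel segmentation-noise scale. Analysis-scale sweeps in
  the tests use 144 cells in a 300 µm box for 36 h so that a full
  50–100-seed replication stays within minutes on one CPU.
* **Topology.** The frame-0 Voronoi adjacency is frozen and evolves only
  through scripted junction swaps. Recomputing adjacency from the diffusing
  centroids would create unscripted exchanges and make the ground-truth
  event list incomplete; freezing it keeps the event list authoritative, at
  the cost of letting geometry and topology drift apart over long movies —
  acceptable because the topology stream, not the geometry, feeds the
  detector. Per-frame Voronoi polygons are still available for shape
  metrics.
* **Scripted T1s.** Event counts are Poisson with the configured rate
  (per interface cell per hour in the rigid-pack regime; gain × v0 per cell
  per hour in the fluid regime); each event swaps one junction quartet,
  permanently, with a cool-down that keeps quartets disjoint within the
  detector's persistence window. Losing cells keep ≥ 3 neighbors and
  gaining cells stay below 10, keeping neighbor counts in the range of real
  tessellations over hundreds of swaps. Congested events may slip by up to
  8 frames; a rate that still cannot be placed raises a diagnostic error.
  In the rigid-pack regime the losing junction joins two interface cells
  and the quartet spans two packs, so junctions flip back and forth at pack
  boundaries instead of depleting.
* **Motion.** Rigid-pack: square blocks of side ≈ L_c share one
  persistent-random-walk velocity of magnitude v0 (heading persistence
  τ = 2 h); within-pack velocity dispersion is exactly zero at zero noise.
  Fluid: independent per-cell persistent random walks at speed v0.
  Crowding: the fluid generator driven by a piecewise speed schedule, with
  no scripted exchanges.
* **What the generators do not emulate:** mechanical force balance, cell
  divisions and extrusions, segmentation errors beyond centroid jitter,
  tracking failures, and optical artifacts beyond additive Gaussian noise.
  Passing tests therefore certify the estimators against data whose
  statistical structure is known, not the segmentation/tracking pipeline
  upstream of them.

## Image phantoms and metrics

Fluorescence phantoms rasterize a Voronoi cell layout (with a background
margin), paint junction bands (cell pixels within 3 px of the cell
boundary — the default band width, comparable to junctional signal width at
typical magnifications), cytoplasm, nucleus disks, and Gaussian puncta, and
store the generating truth. Compartments are pairwise disjoint by
construction and the analysis enforces this. Ratios are background
corrected (median of a supplied background region, else the 1st percentile
of the image, with the method recorded); per-cell-then-average is the
default aggregation with pooled-pixel available by flag. The
cytoplasmic-to-nuclear orientation is reported as printed for the nuclear
exit readout, with the inverse behind a flag. Puncta are detected by a
difference-of-Gaussians band-pass at the spot scale and local maxima above
median + 5×MAD of the band-passed image — robust to cell-to-cell brightness
differences. Fold changes versus control are ratios of group means with a
seeded bootstrap CI.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state. Identical config + seed gives
bit-identical outputs, including through the CLI (verified by checksums).
Units are µm, hours, µm/h everywhere; CSVs carry documented headers and are
validated on read with row-level diagnostics; every CLI run writes a
manifest (software version, config hash, input checksums, stage timings,
accumulated warnings).

## Known limitations

* The frozen-topology design means long movies (≫ 100 h) with high
  exchange rates slowly decouple adjacency from geometry; analyses that
  need both consistent at late times should regenerate or shorten movies.
* PIV is single-pass with a fixed window; strong shear within a window or
  displacements beyond a quarter window are out of scope.
* ξ_v estimation inherits a small negative bias from mean subtraction on
  finite domains; domains ≳ 10× the correlation length keep it within a
  few percent.
* The rigid-pack scaling test addresses only the shape of R_T1(V_rms);
  absolute rates are set by calibration, not predicted.
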