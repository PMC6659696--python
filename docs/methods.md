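# Methods

## Surface model

The organ is modelled as a closed genus-0 surface that is star-shaped about
its centroid and close to a surface of revolution. The surface is described
by a spherical profile R(t, φ): distance from the centroid as a function of
polar angle t (0 = anterior pole, π = posterior) and azimuth φ. Fitting
proceeds from a detected boundary point cloud:

1. **Detection** — voxels above an intensity threshold that are 6-adjacent
   to a below-threshold voxel; since the synthetic membrane is a ridge, this
   yields both the inner and outer boundary of the thresholded shell, whose
   binned mean radius sits on the ridge center (the offsets cancel).
2. **Axis** — principal axis of the cloud; anterior at the minimal axis
   coordinate. A manual `axis_hint` override exists for organs whose A–P
   axis is not the longest (oblate shapes) or when anatomical markers
   dictate the pole.
3. **Profile** — R is averaged on a (t, φ) grid (default 96×96), smoothed
   azimuthally by truncating the Fourier series at 4 harmonics and along t
   by a local quadratic (Savitzky–Golay) filter. Local quadratic smoothing
   is scale-free and exact for conic profiles, which is why spheres and
   spheroids are recovered with ≲0.3% bias; a global penalized spline was
   tried first and rejected because its single smoothing parameter cannot
   serve both low-curvature (prolate) and high-curvature (oblate) profiles.
4. **Poles** — R(0) and R(π) come from even-symmetry regression
   (R ≈ c₀ + c₂t²) on the raw points within the first six angular bins;
   dR/dt = 0 at the poles of any smooth closed surface of revolution, so the
   odd term is omitted. This gives pole positions to ~0.02 μm at 0.2 μm
   voxels, which the aspect-ratio tolerance (±0.01 on a sphere) requires.
5. **Resampling** — the meridian curve (z(t), ρ(t)) is re-sampled uniformly
   in arc length s (chord-summed on an 8192-point grid); the metric tensor
   is obtained by centered finite differences of the embedding f(s, φ)
   (periodic in φ). On the resulting grid g_ss ≈ 1 and g_φφ ≈ ρ² by
   construction; positive definiteness away from the poles is asserted in
   tests.

All areas are ∬√(det g) ds dφ; volumes come either from voxel counting of
the interior mask or from the solid-of-revolution quadrature
∫ ½∮ρ² dφ dz — both are exposed because they fail differently (an open
surface breaks the quadrature route; a mis-thresholded mask breaks the
other).

Charts: a cylinder chart covers polar angles within [cap, π − cap]
(default cap 25°, expressed as a fraction of the meridian); two
azimuthal-equidistant polar charts cover the caps with configurable overlap.
Per-pixel metrics are stored in pixel units so a cell's area is literally
the sum of √det g over its pixels; measuring the same cell in the cylinder
and a polar chart agrees to well under 2% (sub-0.5% at 0.1 μm chart pixels),
which bounds the error of the local-metric linearization used for shapes.

## Per-cell measurements

Cell shape uses the second-moment tensor of the cell's pixels after
rescaling chart axes by the symmetric square root of the metric at the
centroid. Eccentricity is e = √(1 − λ₂/λ₁); this equals
√(1 − (minor/major)²) of the best-fit ellipse and matches a display scale
capped below 1, which a ≥1 aspect ratio could not. Orientation is the angle
of the major eigenvector to the latitudinal direction folded into [0°, 90°]
and is recorded as undefined below e = 0.05, where the direction of a
near-circle is noise. Moments were chosen over boundary-ellipse fitting
because they are robust to the skeleton-width ambiguity of segmented
boundaries; the chart-consistency check above bounds the resulting error.

Regional binning splits the meridian into thirds by arc length (anterior,
middle, posterior); the posterior boundary is inclusive. Orientation
distributions use a Gaussian kernel density estimate reflected at 0° and
90° and renormalized on [0, 90].

## Lattice

Segmentation is Otsu thresholding of the membrane-bright pullback followed
by skeletonization; cells are 4-connected components of the complement,
unified across the φ seam, with regions below 3 μm² discarded (the source
analyses state no minimum size; 3 μm² is an artifact convention, roughly
half the smallest mitotic cell). The lookup table is built from the filled
label field: 2×2 pixel corners where ≥3 labels meet are clustered into
vertices — two corner pixels merge only when one's label set contains the
other's, so twin 3-way junctions joined by a short bond stay distinct —
and each connected component of a label pair's shared boundary is one bond.
On closed charts the polar image rows are treated as single points: bond
runs of a pair that owns a 2-label pole are merged through it, and a ≥3
label pole becomes a vertex. These conventions make V − E + F = 2 hold
exactly on closed synthetic tessellations, and 2E = Σ vertex degrees with
4-way (T2-like) junctions retained as degree-4 vertices.

Neighbor number is the bond count of a face (so two cells sharing two
distinct boundary segments count twice), matching the bond-based polygon
classification. Cells touching a chart cut are flagged `boundary` and
excluded from topology summaries.

## Organ metrics and staging

The aspect ratio divides the pole-to-pole Euclidean chord by the
dorsoventral length, taken as equatorial circumference/π (near-circular
cross-section); the geodesic meridian is available behind a flag but the
chord is the default since it reproduces AR = 2 for a 2:1 spheroid. Arc
cell counts use bands of half the follicle-mean cell diameter around the
full meridian circle (the two half-meridians pooled — a cell near a pole is
close to both halves but is counted once) and around the equator ring; the
meridional count is reported doubled, capturing the entire perimeter.
One-cell-wide arcs carry ~8% counting noise per follicle, so ratio
comparisons should pool follicles or azimuths.

Stage assignment is by epithelial cell number against an ordered boundary
table in which a boundary count belongs to the later stage (650 cells →
stage 6B). The 650-cell midpoint and the 862-cell final count are
measurement-anchored; the remaining shipped boundaries are **illustrative**,
derived by running exponential growth (9.6 h cell cycle) backwards from 862
through the stated stage durations (8.4 h, 4.8 h), and are user-editable
configuration. Stage durations are cycle_length × log₂(N_end/N_start).

## Division orientation

A division event is the endpoint pair of a midbody/daughter-separation
segment in (s, φ); the axis angle is that of the displacement in the local
orthonormal frame at the segment midpoint, folded into [0°, 90°]. The
cytokinesis plane is perpendicular to this axis; the reported convention is
the axis angle. Angles are invariant to endpoint order and to relocating
the φ seam. Uniformity is summarized by a two-sample Kolmogorov–Smirnov
test against a deterministic uniform reference sample (evenly spaced
quantiles), keeping the report reproducible.

## FRAP

Raw channels are double-normalized (background subtraction and reference
photobleaching correction); t = 0 is the first post-bleach frame, and
pre-bleach frames enter only through averaged scalars. The one-phase
association model is fitted by unweighted bounded nonlinear least squares
(Y₀ ∈ [0, 1.2], P ∈ [0, 1.5], K ∈ (0, 10] s⁻¹), initialized from the first
sample, the mean of the final 10%, and a log-linear regression for K.
Confidence intervals are covariance-based (t-quantile × standard error,
delta method for half-time and mobile fraction); the CI method of the
source analyses is unstated, and covariance-based intervals are labelled as
such. At noise s.d. 0.02 on the normalized scale, 500 replicate fits show
<0.2% bias in K and 95–96% CI coverage. The fit assumes reaction-limited
recovery; lateral diffusion is out of scope.

## Synthetic world — what it emulates and what it does not

`make_epithelium` places n seeds on the spheroid (Fibonacci-lattice
initialization, randomized by a global rotation and jitter) and relaxes
them with over-relaxed Lloyd iterations of an anisotropic Voronoi
tessellation: distances are 3D chords shrunk by k = 1/√(1 − e²) along each
cell's elongation axis, which imposes the target eccentricity e and the
orientation bias (von Mises-distributed axis angles; uniform when
unbiased). Membranes are rasterized as a ~2-pixel anti-aliased ridge
(signal 1.0, interior 0.1) plus Gaussian noise — deliberately high-contrast
so plain intensity thresholding replaces the original pipeline's
machine-learning prediction maps.

Ground truth per cell records **both** the generating anisotropy (the
imposed target eccentricity and axis angle) and metric-exact moments of the
realized tessellation measured on a 2× supersampled pre-noise assignment.
The distinction matters: moment eccentricity amplifies tiny anisotropy
(e = 0.15 corresponds to a 1.1% axis-ratio deviation), and any Voronoi
tessellation carries intrinsic packing disorder — polygon-exact moments give
mean e ≈ 0.24 for an icosahedral geodesic tessellation and ≈ 0.39 for
converged Lloyd tessellations, on flat tori as well as spheres. "Round
cells" (target 0) therefore means zero *imposed* anisotropy, not zero
measured moment eccentricity; recovery tests compare measurements against
the realized-tessellation truth, which isolates the measurement error
(~3° in orientation, ~0.5% in area at default settings) from generator
packing noise.

The generator does **not** emulate: microscope optics (no PSF or shot
noise), multi-layer tissue or nuclei, cell-size gradients, temporal
dynamics, or drift. A green test therefore establishes correctness of the
geometry/topology/kinetics pipeline on idealized membranes, not robustness
to real microscopy artifacts.

Determinism: one global seed drives every draw; per-operation sub-streams
are derived from (seed, operation-tag) pairs, so outputs are bit-identical
across runs with equal parameters.

## Numerical choices and degenerate inputs

- Meridian arc length by chord summation on dense grids (error O(h²),
  <0.01% at the defaults); doubling the (s, φ) grid moves L, area and
  volume by <0.2%.
- Otsu threshold by default everywhere a threshold is needed; manual
  override throughout.
- Division events with coincident endpoints, empty label masks, open
  surfaces, all-zero volumes, non-monotone FRAP time bases, and degenerate
  (zero-variance) statistical samples all raise `ValueError` with the
  offending location where applicable.
- Stage tables must be strictly increasing; counts above the last boundary
  get an overflow label rather than an error.

## Known limitations

- Surfaces must be star-shaped about the centroid; multi-lobed organs are
  rejected, not approximated.
- Normal offsets for pullbacks are taken along the inward radial direction,
  an approximation valid for near-spheroids.
- Anisotropic-tessellation ground-truth shapes are raster-measured
  (supersampled), not polygon-exact; isotropic spherical cases can be
  cross-checked polygon-exactly.
- The orientation-recovery guarantee (≤5° mean error) is stated for
  clearly elongated cells (target e = 0.7); at low eccentricity the cell
  axis is intrinsically ill-determined and orientation is reported as
  undefined below e = 0.05.
- Temporal tracking, T1-event detection, and image-based FRAP ROI
  extraction are out of scope.
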