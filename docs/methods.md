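# Methods

## Barcodes and their combinatorics

A barcode is a binary membership vector over an ordered panel of 1–8
fluorescent channels (bit i = conjugate i present on the cell wall). The
all-zero combination is excluded, because an unstained cell cannot be told
apart from a staining failure, so an n-channel panel carries 2^n − 1 codes.
`enumerate_patterns` emits them in ascending binary order with channel 0 as
the most significant bit; this order is part of the contract (cluster→pattern
tie-breaks and file formats rely on it).

## Synthetic section model

`render_sample` draws cells as ellipses on a jittered grid (overlap-free by
construction; requesting more objects than the grid holds is an error).
Geometry defaults emulate yeast profiles in ~100-nm sections imaged at
~100 nm/px: mean radius uniform in 1.8–2.4 µm, axis ratio up to 1.15.

Intensity model, per channel c of cell i with pattern bits b:

* wall ring (outer 35% of the radius): `B_i · b_c + background`,
* interior: `0.3 · B_i · b_c + background`,
* everywhere: additive Gaussian noise, sd = 10% of the nominal ring
  amplitude (clipped at zero), plus a constant background.

`B_i` is log-normal (σ = 0.3, median = the nominal ring amplitude of 100
camera units) and **shared across channels**: total labeling varies strongly
between cells while channel ratios stay tightly correlated, which is exactly
the structure the second normalization step exploits. σ = 0.3 is a tunable
choice — staining heterogeneity is not quantified anywhere we could anchor it.
The faint interior staining stands for cytoplasmic background labeling; it
also guarantees that the median over a *filled* measurement mask scales with
`B_i · b_c` regardless of the exact ring/interior pixel split. No optics are
simulated (no PSF, no chromatic shift), and noise is Gaussian rather than
Poisson — sections are bright and the simpler model keeps the noiseless
contract exact.

The EM frame is an affine image of the LM frame, by default 8× scale and 7°
rotation with a translation that centres the field; this exercises the
registration path with a scale/rotation of the kind met between ~100-nm LM
pixels and medium-magnification EM montages while keeping rendered EM frames
tractable. The class map labels background/cell/hole/debris; holes (bright
disks) and debris (irregular dark clumps) occupy grid slots of their own so
ground-truth object counts stay exact. Control points are a jittered grid
mapped through the true transform with 0.5 px of EM-frame jitter
(configurable), emulating imperfect manual picking.

Everything is a pure function of (config, seed): identical inputs reproduce
every image bit for bit. `render_em=False` skips the EM rasters for large
samples where only the fluorescence path is needed (at 8× scale a
1,500-cell EM frame would be ~0.5 Gpx).

## Cell detection

The cell class of the (label or argmax-of-probability) map is smoothed by
binary opening+closing with a 2 px disk — the raster is edge-padded first so
objects touching the border are not shaved — then split by watershed on the
negated Euclidean distance transform. Markers are regional maxima of the
distance transform (plateaus count once, so a ridge does not fragment an
elongated object), grown by half the configured minimum separation
(default 1.5 µm) so that nearby maxima merge into one seed; the growth uses
a distance-transform threshold, which is cheap at any radius.

Objects are gated on area (default 3–80 µm², the yeast profile range) and
circularity 4πA/P² ≥ 0.6 (perimeter from the marching-squares outline,
clamped at 1 against digitization overshoot); edge-touching objects are
flagged and excluded from `ok` because partial profiles bias both area and
intensity. All thresholds are configuration, not constants: the criterion
(size + circularity) is standard, the specific values are this package's
defaults. Ids are assigned in raster order of the centroids, making output
independent of labelling order and dtype.

## Registration and measurement

`fit_affine` solves the 6-coefficient least-squares problem on ≥ 3
non-collinear control-point pairs (rank check at tolerance 1e−9); residuals
are returned per point and an rms above 5 px logs a warning rather than
failing, since usable fits with one bad pick are common. Transforms compose
and invert exactly (|det| > 1e−12 enforced).

Measurement masks are built in the LM frame: transformed outline, polygon
fill, dilation by round(0.2 µm / pixel size) — the lectin ring sits on and
just outside the wall, i.e. outside the EM-derived outline. Pixels claimed
by more than one cell are removed from **all** claimants (not split), and
pixels on the transformed holes/debris raster are removed too; dropping
contested pixels entirely is the simplest rule that cannot bias any cell's
median. Masks are stored as flat pixel-index arrays so memory scales with
cell area, not field of view. The per-channel statistic is the median, which
is insensitive to the mask straddling ring, interior and a little
background.

## Barcode determination

Step 1, per channel over all cells: `N = (I − min I) / (Q3 − Q1)`, with
quartiles by linear interpolation between order statistics. The IQR is used
instead of the min–max range because it characterizes the distribution shape
without being driven by outliers; the subtrahend is the literal observed
minimum. A channel with Q3 = Q1 is uninformative and raises an error naming
it. Step 2, per cell: `F = N / max_c N`, removing the cell-to-cell labeling
scale; a cell whose maximum is ≤ 0 cannot be scaled and is flagged
`unclassifiable` instead of failing the run. Both steps make the pipeline
exactly equivariant to per-channel affine rescaling of the raw data.

In F-space a cell with bits b sits near b itself (its brightest present
channel normalizes to 1), so the ideal position of each pattern is its bit
vector. Classification is Euclidean k-means (k-means++ initialization, 50
restarts, mandatory seed; k defaults to the number of expected color
combinations) followed by a Hungarian assignment of centroids to ideal
vectors — a bijection is required for barcodes to be well defined, and the
optimal matching is stable under centroid perturbations smaller than half
the minimum ideal–ideal distance. Cells farther from their centroid than the
95th percentile of within-cluster distances are flagged `low_confidence`
(the quantile is configurable; there is no canonical value).

The QC report replaces an interactive review: per-pattern PNG galleries
(every LM channel crop, plus an EM crop when the overview and transform are
given) and a deterministic calls CSV; an override CSV (`exclude` /
`reassign:<bits>`) applies manual corrections non-interactively and marks
them `manual_override`.

## Stereology

With `u_i` the cell cross-section areas and `v_i` the summed organelle
profile areas per cell, the Delesse principle gives the volume fraction as
the ratio of sums V_r = Σv/Σu. Its standard error uses the sampling-theory
ratio-estimator form

    SE = V_r · sqrt( k/(k−1) · [ Σu²/(Σu)² + Σv²/(Σv)² − 2Σuv/(ΣuΣv) ] ),

with the bracket clamped at 0 against floating-point negatives. The cross
term is negative: positive correlation between a cell's area and its
organelle content *reduces* the ratio's variance, and v ∝ u forces SE = 0
exactly. The formula is validated against a nonparametric bootstrap in the
test suite.

Organelle profiles are user-measured ellipses (D1 ≥ D2): A = πD1D2/4 and
Ramanujan's perimeter C = π[3(a+b) − √((3a+b)(a+3b))] on the semi-axes,
which is exact for circles and accurate to ≪ 0.1% up to aspect ratio 5.
Surface-to-volume uses S/V = (4/π)·ΣC/ΣA — the classical boundary-length
relation restricted to the organelle phase; for sliced spheres of radius r
it converges to the true 3/r. A configuration switch drops the 4/π constant
and returns the bare ΣC/ΣA, since the quantity is sometimes reported without
it; the default includes the constant because S/V is dimensionally 1/length.

The sphere-slicing validator cuts each synthetic cell (radius log-normal,
default mean 2 µm, CV 0.10) with one plane uniform over its own diameter;
contained organelle spheres (count Poisson(2), radius log-normal mean
100 nm, CV 0.2, centres uniform in the ball that keeps them fully inside)
contribute circular profiles when intersected. The exact 3D fraction
Σ(4/3)πr³ / Σ(4/3)πR³ is returned alongside. One-plane-per-cell sampling
weights cells by 1/diameter relative to true volume-uniform sectioning, so
at nonzero cell-size CV the Delesse estimate carries a small bias
(≈ exp(3·ln(1+CV²)) − 1, about 3% at CV 0.10) — well inside the estimator's
sampling error at the sizes used here, and absent for monodisperse cells.
The defaults (10,000 cells in the recovery checks, 200 cells × 2,000
replicates in the bootstrap comparison) keep the full validation under a
minute.

## Navigator export

Navigator files are parsed as autodoc text: a verbatim preamble plus
`[Item = label]` sections of `Key = value` lines. Unknown keys pass through
untouched so written files remain usable by the acquisition software;
the canonical serialized form (one blank line before each section) round
trips byte-for-byte. Pixel→stage mapping is
`stage = raw_stage + M · (p − map_center)` with M the map's stage-per-pixel
matrix; whether image y (downward) maps to stage −y is an explicit flag
(default: inverted), because the convention differs between installations —
the round-trip identity holds under either setting. Exported points carry
`Acquire = 1`, a `DrawnID` reference to the map, the map's z, and labels
`<pattern>_<id>`.

## What passing tests do and do not show

The generator reproduces the *structure* that the method relies on —
correlated per-cell brightness, binary channel membership, a rigid LM↔EM
relation, segmentable distractors — but not real-data difficulties:
out-of-focus light and chromatic shifts, section wrinkles and non-affine
distortion, aggregated stain, touching cells (grid placement keeps profiles
separate; the watershed split is exercised only on constructed fixtures),
or genuinely ambiguous staining. Classification accuracy on the synthetic
defaults is therefore an upper bound, not a field estimate; on real material
the QC review exists precisely because a few percent of cells are
ambiguous. Morphometry assumes profiles are measured consistently and that
organelle content is independent of cell size; the SE covers sampling error
only, not measurement error of the by-eye ellipse approximation.

## Numerical choices

* Quantiles: linear interpolation between order statistics, everywhere.
* k-means: k-means++ with 50 restarts and an explicit seed; ties in the
  Hungarian assignment break by pattern binary order.
* Affine fit: `numpy.linalg.lstsq`; collinearity detected by a rank check
  at relative tolerance 1e−9.
* Circularity clamped to 1; watershed marker merge radius ⌊separation/2⌋ px.
* Degenerate inputs prefer flags over failures at the per-cell level
  (empty mask → NaN row; unscalable cell → `unclassifiable`) and loud
  errors at the dataset level (uninformative channel, k > cells, orphan
  measurement ids).
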