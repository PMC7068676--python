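# Methods

## The analysis model

The unit of analysis is a *trace stack*: an ordered series of binary planes,
one per confocal optical section, whose foreground pixels are 1-pixel-wide
lines drawn over the long axes of elongated muscle cells. The pipeline
assumes (a) traces are approximately one pixel wide, (b) each plane was
traced independently (no 3-D linking is attempted), and (c) trace pixels
carry no intensity information — a drawn vector is a set of equally weighted
pixels.

Processing order per plane:

1. **Junction removal.** Every foreground pixel with ≥ 3 foreground
   neighbors under the chosen connectivity is set to background in a single
   simultaneous pass. This is the standard skeleton-junction criterion; it
   covers both fiber-fiber overlaps and morphological branch points, which
   are indistinguishable at the pixel level. Exactly one pass is applied:
   iterating to a fixpoint can eat into long fibers at staircase diagonals,
   while one pass already disconnects crossings of 1-pixel traces.
2. **Component extraction.** Connected components of the pruned plane
   (default 8-connectivity, since hand-drawn diagonal strokes are
   8-connected chains) become fiber segments. Components shorter than
   `min_segment_length` are junction debris and are dropped; drops are
   tallied in the log. Segment ids follow raster order of each component's
   first pixel, then plane order, making decomposition deterministic.
3. **Orientation.** Each segment's unweighted second-order central moments
   μ₂₀, μ₀₂, μ₁₁ about its pixel centroid give the principal-axis angle
   θ = ½·atan2(2μ₁₁, μ₂₀ − μ₀₂) — the branch-free equivalent of the leading
   covariance eigenvector, and equal (verified in the tests against a
   projection-based scan) to the axis of maximal projected variance. Angles
   live in the image frame: x rightward, y downward, θ measured from +x
   toward +y. Fibers are axial objects (θ ≡ θ + 180°), so angles are reduced
   modulo 180° and binned into `n_bins` half-open bins [k·w, (k+1)·w),
   w = 180°/n_bins, the upper edge wrapping to bin 0.
4. **Maps and statistics.** Binary projections are per-pixel maxima over a
   selected section range. Hue-coded projections paint each segment with its
   bin's LUT color; order over overlapping planes is "topmost (largest
   plane index) wins", a simple deterministic rule. Orientation order is the
   nematic order parameter on doubled angles,
   S = |Σ w e^{i2θ}| / Σ w, with the mean axis ½·arg(Σ w e^{i2θ}).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `connectivity` | 8 | – | drawn diagonal strokes are 8-connected; 4 available for axis-aligned tracings |
| `min_segment_length` | 5 | px | suppresses junction debris while keeping short myocyte traces; all drops logged |
| `thinning` | off | – | optional skeletonization pre-step for traces thicker than 1 px |
| `n_bins` | 32 | – | the analysis discretizes 0–180° into 32 equal bins of 5.625° |
| LUT hue span | 0° → 300° | HSV deg | rainbow ruler; stopping short of 360° keeps bin 0 and bin 31 visually distinct despite the axial wrap |
| histogram/order weighting | per-segment | – | the traced unit is the whole vector; per-pixel mode gives longer fibers proportionally more weight |
| `match_radius` (recovery) | 3 | px | a recovered segment shares its fiber's pixels, so centroids agree to well under a pixel; 3 px tolerates clipping |

Stack depth is `n_sections × z_spacing` (each section owns one spacing's
worth of depth), reported to 0.01 µm; geometry travels in a plain-text
sidecar because TIFF resolution-tag dialects are unreliable (conflicts are
logged and the sidecar wins). Where a published legend's printed depth
disagrees with the exact product by a rounding residue, the exact product is
reported.

## Numerical choices

- **Degeneracy.** A segment with |μ₂₀ − μ₀₂| and |μ₁₁| both below
  10⁻⁹ × pixel count (or fewer than 2 pixels) has no preferred axis and is
  flagged degenerate rather than given a noise-driven angle. Degenerate
  segments are retained, painted a reserved neutral gray in renderings, and
  excluded from histograms and order statistics.
- **Mean axis at S = 0.** For a perfectly balanced field (resultant below
  10⁻¹²) the mean axis is undefined and reported as `None`.
- **Binning edges.** Half-open bins with floor assignment; a floating-point
  angle landing exactly on 180° maps to bin 0, and a value infinitesimally
  below 180° clamps to the last bin.
- **Comparisons.** `compare_conditions` reports per-map S, mean axis,
  histograms and ΔS but deliberately attaches no p-value: the order claims
  it supports are qualitative, and a permutation test over segment labels is
  a straightforward extension left to the caller.

## The synthetic generator

`generate_field` emulates the statistical structure of traced limb data:
one or more rectangular spatial clusters, each placing `n_fibers` straight
1-pixel Bresenham lines with centers uniform in the cluster region, sections
uniform over the stack, lengths uniform in `length_range`, and axial angles
drawn so that 2θ is von Mises with mean 2·mean_axis and concentration κ —
the standard axial-data construction, spanning isotropic (κ = 0, uniform on
[0°, 180°)) to perfectly aligned (κ ≥ 10⁸ is treated as the zero-dispersion
limit and returns the mean axis exactly). All draws derive from one seed,
with per-cluster substreams so one cluster's output is stable when another
changes; identical spec + seed reproduces the stack bit for bit.

With `allow_crossings=False`, a candidate fiber that touches (shares or is
8-adjacent to) previously placed pixels in its plane is redrawn up to 100
times, then dropped with a logged count; adjacency, not just overlap, is
excluded so that every placed fiber stays a single connected component and
ground-truth recovery is exact. A drop rate above 50% aborts with advice to
enlarge the region or reduce the count. Default fixture scales (lengths
15–40 px, tens to hundreds of fibers per cluster, 512×512 planes, ~10–12
sections) are stated as test fixtures, not biological measurements.

What the generator does **not** emulate: fluorescence images, PSF blur,
tracing error, curved fibers, fiber width variation, spatial density
gradients (compaction enters only through region size), or developmental
dynamics. Passing tests therefore demonstrate correctness of the
decomposition → moments → binning → statistics chain on fields with known
truth; they do not validate manual tracing quality on real images.

Measured on the generator itself: Bresenham rasterization biases a straight
fiber's recovered axis by up to ~6° at 10 px length, ~2° at 30 px and ~1.6°
at 40 px, so the zero-dispersion recovery bound of 2° is asserted for
30–40 px fibers; errors are near-symmetric, so cluster *mean* axes are
recovered to well under 1° with ≥ 50 fibers.

## Design choices where the design was open

- The toy plus-sign decomposition is connectivity-sensitive: under
  4-connectivity only the center pixel is a junction and the four 2-pixel
  arms survive; under 8-connectivity the four pixels diagonal to the arms
  also qualify and the arms reduce to single pixels. Both behaviors are
  tested; the pipeline default stays 8 because real drawn strokes are
  8-connected.
- Overlap removal and branch-point removal are implemented as the single
  junction-pixel rule; nothing distinguishes the two cases at pixel level.
- The angle frame (y down, θ from +x toward +y) is chosen for internal
  consistency with raster geometry; any display flip is a viewer concern.
- Rendered images are written with the y-axis as stored (no flip).

## Problem sizes

The test suite and the reproduction script run synthetic fields of 30–500
fibers on 256²–512² planes with 8–12 sections, 1,000 random segments for
the axis-oracle comparison, and 10,000 draws for the isotropic-limit and
uniformity checks — sizes at which every reported statistic is stable to
well within its asserted tolerance.

## Known limitations

- No 3-D fiber linking: a fiber spanning several sections is counted once
  per section, exactly as in per-plane tracing.
- No gap closing: a fiber severed by junction removal stays split; counts of
  segments exceed counts of fibers wherever crossings exist.
- Very short segments (< ~10 px) carry several degrees of rasterization
  noise in their individual angles; statistics over many segments are
  unaffected.
- The hue projection is categorical by bin; within-bin angular differences
  (< 5.625°) are invisible by construction.
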