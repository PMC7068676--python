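# fibermap

Orientation mapping of hand-traced muscle-fiber z-stacks.

During limb development, elongated muscle cells (myocytes and nascent
myofibers) progressively align into clusters with shared orientation — the
precursors of individual muscle bundles. A standard way to quantify this is
to trace each cell's long axis as a 1-pixel line on every optical section of
a confocal z-stack, and then ask, plane by plane and fiber by fiber, which
way each trace points and how ordered the resulting field is.

`fibermap` implements that analysis for anyone working with binary trace
stacks (developmental biologists, image analysts):

1. **Decomposition** — each binary plane is pruned of junction pixels
   (foreground pixels with ≥ 3 foreground neighbors, i.e. fiber crossings
   and branch points) and split into connected components, one retained
   segment per traced fiber stretch.
2. **Orientation** — each segment's axial angle comes from its second-order
   central moments,

   θ = ½ · atan2(2 μ₁₁, μ₂₀ − μ₀₂),   μ_pq = Σᵢ (xᵢ − x̄)ᵖ (yᵢ − ȳ)ᵍ,

   normalized to [0°, 180°) and discretized into 32 equal bins (width
   5.625°).
3. **Mapping** — binary maximum projections over any section range, and
   hue-coded projections in which every segment is painted with its bin's
   color from a rainbow look-up table.
4. **Statistics** — the nematic order parameter of a set of axial angles
   {θᵢ} with weights {wᵢ},

   S = |Σ wᵢ e^{i·2θᵢ}| / Σ wᵢ,   mean axis = ½ · arg(Σ wᵢ e^{i·2θᵢ}),

   which is 1 for a perfectly parallel field and → 0 for an isotropic one,
   plus side-by-side condition comparisons (ΔS).
5. **Synthetic fields** — a seeded generator of ground-truthed trace stacks
   (clusters of Bresenham-rasterized fibers with von Mises axial dispersion),
   so the whole pipeline is testable without any imaging data.

## Worked example

```python
import fibermap as fm

# two clusters of fibers at 30 deg and 120 deg, tightly aligned (kappa = 100)
spec = fm.SyntheticFieldSpec(
    height=256, width=256, n_sections=8, seed=42,
    clusters=(
        fm.ClusterSpec(mean_axis_deg=30.0, kappa=100.0, n_fibers=60,
                       region=(8, 8, 248, 120), length_range=(15.0, 40.0)),
        fm.ClusterSpec(mean_axis_deg=120.0, kappa=100.0, n_fibers=60,
                       region=(8, 136, 248, 248), length_range=(15.0, 40.0)),
    ),
)
stack, truth = fm.generate_field(spec)
omap = fm.analyze_stack(stack)          # prune -> segment -> moments -> bins

print(fm.axial_order(omap).order_parameter)      # whole-field S
report = fm.recovery_report(truth, omap)         # score against ground truth
```

Output for this spec:

```
segments: 120  (degenerate: 0)
whole-field order parameter S = 0.002
match rate = 1.00, mean |angle error| = 0.84 deg
cluster 0: true axis 30.0 deg, recovered 29.92 deg
cluster 1: true axis 120.0 deg, recovered 119.79 deg
modal bins: [5, 21]
```

Every generated fiber is recovered as exactly one segment (match rate 1.00)
and its axis to better than a degree on average. The *whole-field* S is near
zero even though each cluster is tightly ordered — the two mean axes are
perpendicular, so their doubled-angle resultants cancel; restricting to one
cluster gives `S = 0.995, mean axis = 29.92 deg`. The angular histogram's
modal bins 5 and 21 are exactly where 30° and 120° fall at a 5.625° bin
width. Use `fm.render_colored_projection(omap)` /
`fm.project_binary(omap)` for the hue-coded and binary projections, and
`fm.write_segment_table(omap, path)` for the per-fiber table.

Real data enter through `fm.load_trace_stack(path, geometry)` (multi-page
TIFF of binary planes; any nonzero sample is foreground) with the physical
calibration in a key-value sidecar read by `fm.read_geometry`. Depth
bookkeeping follows `total_depth = n_sections x z_spacing`, e.g.
`fm.total_depth(46, 1.51) == 69.46` µm.

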