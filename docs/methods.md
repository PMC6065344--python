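# Methods

## Data model and conventions

A digitised mark is four points in μm: `p1–p2` span the length axis, `p3–p4`
the width axis. Length and width are the Euclidean distances between the two
point pairs; the width axis is *not* constrained to be perpendicular to the
length axis, since an operator tracing an irregular scar may not place it so.
Pixel coordinates are 0-based, origin top-left, x rightward, y downward;
physical coordinates are μm in the same orientation. Scale calibration is
`known_length_um / |ref_a − ref_b|` from two pixel positions on the embedded
metric reference, so it is exact up to the operator's point placement.

Colour images are collapsed to grayscale with the BT.601 luminance weights
(0.299, 0.587, 0.114) after normalising integer samples by their dtype
maximum; intensities everywhere are floats in [0, 1].

## Classification rules

With thresholds `pit_scr_ratio` (default 4, dimensionless — although
sometimes quoted with a μm unit, the length/width ratio is unitless),
`sm_lg_pit_um` (8 μm) and `fi_co_scr_um` (3 μm):

- ratio ≤ `pit_scr_ratio` → pit, else scratch (boundary inclusive on the pit
  side);
- pit diameter ≤ `sm_lg_pit_um` → small pit, else large (inclusive small);
- scratch width ≤ `fi_co_scr_um` → fine, else coarse (inclusive fine).

Two genuinely open points were decided here. First, the pit *diameter* is
taken to be the mark's length axis: for near-isodiametric pits the two axes
are similar, and the length is always the first measured axis. Second, the
fine/coarse boundary is inclusive on the fine side, mirroring the small/large
pit rule. No `length ≥ width` constraint is imposed; a mark wider than long
has ratio < 1 and is a pit.

Classification is scale-invariant: multiplying all coordinates and both μm
thresholds by a common factor changes nothing. Manual overrides (a
`manual_label` column in the marks CSV, or an edits file applied through
`reclassify` / the `check` subcommand) are honoured with `source="manual"`.

### Staleness contract

A `Classification` carries a token; pair results record the token they were
computed under. `reclassify` invalidates the old object, after which both
pair detection and `summarize` refuse it, and `summarize` refuses pair
results whose token does not match — manual edits therefore force a re-run of
pair detection before a summary can be produced. The CLI `run` and `check`
flows recompute pairs after edits automatically.

## Scratch-pair geometry

Each scratch contributes the infinite line through its length-axis endpoints
(slope/intercept, with an explicit vertical representation rather than a
large-slope approximation). For a pair:

1. If the directions differ by less than 1e-9 rad the lines are treated as
   exactly parallel (this also guards against overflow in the intersection
   coordinates) → **parallel**.
2. Otherwise the line intersection is computed, and `d_a`, `d_b` are the
   distances from it to the nearest point of each length-axis *segment*.
   The pair is **crisscross** iff `d_a ≤ T` and `d_b ≤ T` with
   `T = multiplier × side_um` (default multiplier 2, i.e. 400 μm for a
   200 × 200 μm working area), else parallel.

The threshold is a length because a distance is being compared; requiring
the intersection to be near *both* segments encodes that a physical cross
involves both features. Both choices are exposed (`multiplier`, and the
distances are to segments, documented here) since the tallies are sensitive
to them. The crossing angle is the acute angle between direction vectors,
`atan2(|u×v|, |u·v|)` in (0°, 90°]. Results are canonical in the unordered
pair (ids sorted), so the relation is symmetric by construction, and every
scratch pair receives exactly one relation.

`segment_intersects` is the standard counter-clockwise orientation test with
explicit collinear handling; it supports the crossing tallies and implies
crisscross for any positive threshold.

## Summary table

Densities divide counts by the *nominal* working-area size `(side/1000)²`
mm², not the rounded pixel crop, so they stay exact under resampling
(17 pits / 0.04 mm² = 425 regardless of the pixel grid). `N.Ps` counts
parallel *pairs*; `N.Xs` counts *scratches* involved in ≥ 1 crisscross pair;
`%Ps` / `%Xs` are percentages of scratches involved in ≥ 1 pair of the
respective relation. Both conventions' raw ingredients (pair counts and
involved-scratch counts) are retained on the table. SDs use the sample
(n − 1) denominator and are undefined for groups of fewer than two marks;
undefined cells export as `/`. Exports round percentages to one decimal,
densities to integers and means/SDs to two decimals; full precision stays on
the in-memory table.

## Rendering

Overlays draw each mark's length and width segments plus endpoint disks in
its subcategory colour over the grayscale image, at the input's exact pixel
dimensions. μm positions map to pixels by dividing by the scale and rounding
to nearest. Unset style sizes auto-scale: line width `max(1 px, width/500)`,
point radius one pixel larger. Out-of-bounds marks are clipped with a
warning. Rendering is deterministic, so repeated runs are byte-identical.

## Synthetic generator

The generator emulates the two study conditions the package is exercised
under: tens of marks in a 200–400 μm square working area, pit diameters
3–35 μm, scratch lengths 15–150 μm (bounded by what fits straight inside the
area) with widths 0.5–8 μm, and scratch orientations drawn from a mean
direction with Gaussian jitter (default 8° SD — a strongly oriented,
grazer-like pattern; 0° makes all pairs exactly parallel). Default counts
are 9 small pits, 8 large pits, 20 fine and 14 coarse scratches. Every
generated mark keeps a 5% relative margin from each classification boundary,
so the automatic classifier recovers the ground-truth labels exactly — this
is a designed property, and passing it validates the threshold logic and the
plumbing, not the biological realism of the marks. Sizes are uniform within
their ranges; pits draw a length/width ratio uniformly in [1, 0.95 × ratio
cut] with a uniform random orientation. Infeasible configurations (ranges
that straddle a threshold, or marks that cannot fit in the area) are
rejected at construction.

Rasterisation paints dark (0.15) capsule-shaped features on a bright (0.85)
background with Gaussian noise (SD 0.04), enough to exercise image I/O and
rendering. It does not attempt enamel texture, illumination gradients,
focus blur or mark overlap occlusion — so tests passing on synthetic rasters
say nothing about *detecting* marks in real images, which is out of scope:
mark positions always enter via the coordinate CSV.

## Numerical choices

- Crop rounding: the μm square maps to the nearest integer pixel window
  (corner and side rounded independently); the nominal area is used
  downstream.
- Marks CSVs are written at full float precision; round-trips agree to
  < 1e-6 μm (observed ~1e-13).
- Classification boundaries compare the measured axis lengths directly;
  ties go to the small/fine/pit side deterministically.
- All randomness flows through explicitly seeded `numpy` generators; there
  is no global RNG state. Problem sizes in the tests and the acceptance
  script (≈ 50-mark sets, 1000 geometry pairs) are the study-condition
  sizes themselves, so the whole suite runs in seconds.

## Known limitations

- No automatic mark detection from pixels; the operator's digitisation is
  the input.
- The distance-to-segment reading of the crisscross rule and the
  `T = 2 × side` threshold are documented interpretations of an ambiguous
  verbal rule; the multiplier parameter lets users explore alternatives.
- `%Ps`/`%Xs` follow the involved-scratch convention; reports using a
  pair-count convention will differ (both ingredients are exported).
- Working areas are axis-aligned squares only.
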