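# Methods

## The measurement

The package treats a leaf as two binary rasters at a standard magnification
of 10 µm per pixel: the venation network (minor veins, nominally 3 px wide)
and the structural vein (the midrib; in hierarchical leaves also the primary
and secondary veins).  The structural vein is protected absolutely — no
attack ever removes its pixels — and pixels present in both masks are
classified as structural, so the attackable set is `network \ structural`
and its pristine size N is fixed when the leaf is loaded.  All fractions are
reported relative to this N: both the surviving fraction and the attached
fraction are "of the original venation network", which keeps curves from
different attacks on one leaf directly comparable.

Attachment uses 8-connected component labelling on the union of the damaged
network with the structural vein.  Every component containing at least one
structural pixel counts as attached; the structural tracing is not required
to be a single component (tapering joints can rasterize into several).
Labelling itself is delegated to `scipy.ndimage.label` and re-numbered into
row-major first-encounter order so label grids are deterministic; the test
suite checks it pixel-for-pixel against a hand-written flood-fill oracle.
Under 8-connectivity, removing one pixel from an unbroken 3-px vein never
severs it; severing requires a complete anti-chain of removals, which is why
vein-level damage shows a sharp percolation-style collapse rather than
immediate degradation.

## Attack operators

**Vein attack.**  Exactly `round(p·N)` attackable pixels are removed,
sampled uniformly without replacement (Python's `round`, banker's at ties).
An exact count rather than per-pixel Bernoulli draws makes the surviving
fraction equal p up to half a pixel and keeps replicates reproducible; at
these network sizes the two schemes are indistinguishable in distribution.

**Blade attack.**  n hole centres are drawn i.i.d. uniformly over the
bounding box of the leaf's foreground — the least speculative stand-in for
the blade outline, which the rasters do not record.  Each hole removes the
attackable pixels under a 60-px disc kernel built nearest-to-origin first
with lexicographic (row, col) tie-breaking; the 60-px disc is slightly
asymmetric (61 lattice points lie within squared radius 18, so one of the
four corner ties is dropped) but deterministic and exactly 60 px, honouring
the stated hole area literally.  Holes may overlap (no double counting) and
are clipped at the image border rather than re-sampled, so hole centres
remain uniform and edge damage is not biased.

## Campaigns, binning, robustness

A campaign runs 250 attacks per leaf and kind, drawing the intensity afresh
each time: p ~ Uniform[0, 1] for vein attacks, n ~ discrete Uniform{0..2000}
for blade attacks.  The attack parameter is sampled and the achieved damage
measured — for blade attacks on a large network the achieved range may not
reach zero, and this is surfaced (a warning, and the score records how many
bins contributed) rather than hidden.  Outcomes are binned by surviving
fraction into 20 equal bins over [0, 1], each bin closed on the left and the
last closed at 1; bin SDs use the population denominator (the whiskers are
descriptive, not inferential).  The robustness score is the sum of the bin
means of the attached fraction, a 20-point Riemann proxy for the area under
the response curve, bounded by 10.5 and equal to 10.0 in the
graceful-degradation limit.  Empty bins are excluded from the sum — the mean
of an empty bin is undefined — and their number is reported.

One master seed spawns one child seed per attack by counter
(`numpy.random.SeedSequence`), and every outcome records its own seed, so
any single attack can be replayed in isolation and campaigns are pure
functions of (config, inputs, master seed).

## The synthetic generator

The generator emulates the raster conventions of traced leaves while
keeping the geometry schematic; what the damage analysis responds to is
topology and density, not outline fidelity.  All three classes share an
elongate rectangular pinnule-like blade, 640 × 120 px (6.4 × 1.2 mm) by
default, with a straight 12-px midrib and 3-px network veins:

- **branched** — laterals leave the midrib every 32 px and dichotomize
  twice (depth 2) through axis-aligned T-junctions, never reconnecting;
  the leaf is loop-free by construction.
- **net** — vertical laterals every 16 px crossed by horizontal veins form
  a rectangular mesh whose hole count equals the configured cell count
  exactly (`net_loop_count`); every vein contact is drawn at full raster
  width, i.e. all anastomoses are functional loops.
- **hierarchical** — a midrib tapering from 12 px to 4 px plus nine 5-px
  structural secondaries crossing the blade, over a minor-vein mesh at
  12-px spacing (denser than the net class, as angiosperm minor venation
  is).

The `seed` jitters lateral/mesh placement within bounds that provably leave
the line counts — hence the loop counts — unchanged, so replicate leaves
differ in geometry but not topology.  Every generator validates its output:
pristine leaves are fully attached (attached fraction exactly 1.0) or
generation fails loudly.

Two deliberate departures from a morphometric reconstruction: the blade is
rectangular rather than a tapered outline so that the configured mesh-cell
count maps exactly onto the measured loop count, and the default blade is
small.  The attack intensities are fixed constants of the experiment design
(p up to 1, up to 2000 holes of 60 px), so the leaf size determines how deep
into the damage axis a blade campaign can reach; the default canvas is sized
so blade attacks sweep most of the response curve, comparable to the span of
the published curves this analysis format comes from, rather than probing
only the first bins.  Mesh spacings (16 and 12 px, i.e. 0.16 and 0.12 mm)
sit at the areole scale of real fine anastomosing venation.

### What the generator does and does not emulate

It reproduces the raster conventions, the protected-structural-vein
topology, the three architecture classes and realistic vein densities.  It
does not reproduce tracing artifacts of real scanned material: curved and
ragged vein outlines (whose occasional sub-3-px pinches make real networks
substantially more fragile to pixel-level attack than clean strokes),
vein-width heterogeneity within the network, irregular polygonal meshes, or
species-specific outlines.  Passing the synthetic tests therefore
demonstrates correctness of the machinery and the qualitative
branched < net < hierarchical robustness ordering, not quantitative
agreement with any real tracing.

One qualitative pattern from the literature this generator does **not**
reproduce: on these schematic leaves the blade-attack robustness exceeds the
vein-attack robustness for the net and hierarchical classes but *not* for
the branched class.  The mechanism is geometric: a 60-px hole covering a
3-px vein severs it with certainty, whereas random removal of a fraction q
of pixels severs a width-3 8-connected strip only at a rate ~q³ per
position, so at every survival level above ~0.73 a hole attack disconnects
strictly more of a loop-free tree than a vein attack does, and below that
level both have fully collapsed; summing bin means preserves the pointwise
inequality.  Loopy networks escape this because holes sever single mesh
edges that reroute, while deep pixel removal destroys all paths at once.
Reported analyses of real traced branched leaves find blade robustness
slightly above vein robustness instead; their vein-attack collapse begins
much earlier (around 0.95 surviving) than clean schematic strokes allow,
consistent with rasterization raggedness dominating real vein-level
fragility.  See the response-curve figures produced by the campaign runner
when comparing.

## Numerical choices and degenerate inputs

- Binarization thresholds at mid-range of the image dtype with an explicit
  dark/light foreground flag, never inferred from palette statistics.
- Rasterized strokes include every pixel centre within width/2 of the
  polyline plus a densely sampled rounded spine, guaranteeing a single
  8-connected component even at width 1.
- Empty masks are rejected at load; a pristine attached fraction below 1
  (stray tracing pixels) warns and is reported, with an optional
  prune-small-components switch that is off by default — the analysis
  pipeline itself does no cleaning.
- `f_remain = 1` outcomes land in the last bin (closed at 1); single-sample
  bins report SD 0; empty outcome lists produce header-only files and
  all-NaN binned curves without error.
- A campaign leaf that fails its load invariants is logged and skipped; the
  campaign continues.
- Per-attack seeds are spawned by counter from the master seed and kept
  below 2³¹.

## Problem sizes

Default study conditions: three venation classes × two attack kinds × 250
attacks, on 640 × 120 px leaves with (12–40)×10³ attackable pixels; a full
three-seed replication of the cross-class comparison is ~4,500 labelled
attacks and runs in well under a minute on one CPU.  Larger canvases only
change runtime linearly in pixel count; the test suite and the acceptance
script both use the default sizes.

## Known limitations

- The attachment metric is purely topological; no fluid-flow (hydraulic)
  model is included, so "function retained" means connectivity, not
  transport capacity.
- Hole feeding is the only folivory geometry; margin feeding,
  skeletonization, mining and galling are out of scope.
- Vein-level removal is spatially uniform; processes that nucleate in large
  veins and spread (embolism) are not modelled.
- The blade proxy for hole placement is the foreground bounding box, not a
  reconstructed leaf outline.
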