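# Methods

## Scope and model

`sporemorph` measures the projected outlines of quasi-spherical spores
arranged in a monolayer and imaged in brightfield: dark objects on a
bright, near-uniform background (the acquisition the pipeline is
calibrated for sets the background to 90% of the 8-bit maximum). All
morphometry is two-dimensional; a spore's size is summarized by the
equivalent-circle diameter d = 2·√(A/π)·s of its pixel area A at pixel
scale s (µm/px), and a spore's volume by the sphere π·d³/6. Diameter
populations are modelled as one- or two-component gamma mixtures: spore
size distributions are right-skewed, and for a fitted gamma(k, β) the mode
(k−1)/β is taken as the average-size measure rather than the mean, with
skewness 2/√k.

Key assumptions: spores do not overlap in depth (stacked spores cannot be
separated by any 2-D cut, and overdense tiles are excluded by BScore
instead); tile overlap is negligible, so no cross-tile deduplication is
attempted; spore walls are smooth — ornamentation (spines, ridges) is
neither rendered by the generator nor corrected for by the measurement.

## Tile quality scores

IScore = 100 · (95th percentile of the grayscale)/max. The percentile sees
past the dark minority of spore pixels, so it tracks illumination rather
than content; exclusion is relative to the per-slide **median** IScore
(±10% by default) so that the very outliers being flagged cannot drag the
reference. BScore maps the mean grayscale linearly onto 0–100 between two
anchors: `bright_ref` = 0.9·max (the background setting) and `dark_ref` =
0.3·max (the typical spore paint level, i.e. a field completely covered by
spores). Both anchors are configuration, because they describe empirical
extremes of a particular acquisition setup; the default exclusion rule is
BScore < 50. Grayscale is the unweighted RGB mean throughout.

## Segmentation

The trainable path is a random forest (100 trees, unlimited depth, fixed
seed) on a per-pixel filter bank: raw grayscale plus, for each scale
σ ∈ {1, 2, 4} px, a Gaussian smoothing, its gradient magnitude, and a
difference of Gaussians (σ vs 1.6σ) — 10 planes. Two classes only;
contaminants are removed later by shape rules, which is more robust than
teaching a pixel classifier the difference between a spore wall and a
bubble wall. The fallback path thresholds the grayscale: Otsu's
between-class criterion finds the two classes, then the cut is moved to
the midpoint of the class means. With strongly unequal class sizes Otsu's
own cut bites visibly into the minority (spore) class — on rendered disks
it produced a systematic −0.16 µm diameter bias — whereas the mean
midpoint crosses an anti-aliased edge at 50% area coverage and leaves
pixel-count areas unbiased. A contrast guard (class separation ≥ 10% of
the intensity range) returns an empty mask on spore-free tiles instead of
thresholding noise.

Mask cleanup removes components below 20 px (far below any plausible
spore; real size filtering is morphometry's job) and fills interior holes
only up to 64 px: spore interiors contain at most pinhole noise, while the
bright lens center of an air bubble is a large hole that must stay open so
the bubble keeps its ring shape for the circularity filter.

## Separation of touching spores

The structure tensor (the Gaussian-windowed outer product of the intensity
gradient, integration scale ≈ modal diameter/10, pre-smoothing 1 px)
separates outlines from junctions by its eigenvalues. Along an isolated
smooth outline all gradient energy shares one orientation and the smaller
eigenvalue stays near zero; in the two acute-angled corners where the
outlines of touching spores meet, two orientations coexist in one window
and the smaller eigenvalue spikes — 4–12× above anything an isolated
outline produces on rendered oracles. The *larger* eigenvalue was
evaluated first and rejected: it responds to every edge, and at the
junction it is actually ~25% *weaker* than on a clean outline because the
thin bright wedge between touching spores washes out locally. Boundary
handling is mirror-padded; the default constant padding of the tensor
filters produces huge spurious corner responses at tile borders.

The eigenvalue threshold is calibrated at run time on a rendered
isolated-disk tile of the expected modal diameter at the scene's contrast
and noise: threshold = 3 × that map's maximum. By construction isolated
outlines can never trigger a junction; touching pairs respond severalfold
higher. Thresholded regions must lie within 3 px of mask foreground
(corner responses peak in the background wedge just outside the mask).
Centroids are paired greedily by ascending distance, each used once,
within 0.6 × the modal diameter in px (junction corners of touching equal
disks sit about one chord apart); each pair is joined by a Bresenham
(8-connected) 1-px line painted as background. Labeling downstream uses
4-connectivity, so a 1-px 8-connected cut is guaranteed to disconnect.

## Morphometry

Measurements per labeled object: area (pixel count), perimeter, ellipse
axes from second central moments, circularity 4πA/P² (clamped at 1),
AR = a/b, roundness 4A/(πa²), solidity A/A_hull, and mean/sd/mode/min/max
per RGB channel (mode = most frequent integer intensity, ties toward the
lower value). Two modes: `outline` (area/perimeter from the pixel region)
and `ellipse` (area πab/4 and Ramanujan perimeter from the fitted
ellipse); the two agree within 2% on circular objects.

The outline perimeter is the length of the marching-squares sub-pixel
contour after a 5-point circular moving average. Naive boundary-pixel
counting overestimates smooth perimeters by up to 25% and pushes genuinely
round rasterized spores below any usable circularity cut; Crofton
multi-directional estimates are excellent on disks (+0.2%) but
systematically short on axis-aligned polygons (−5.5%, inflating a square's
circularity 12% above π/4). The smoothed contour stays within ~1% on disks
and ~2% on squares, and it includes interior hole boundaries, so bubble
rings score the low circularity that removes them.

Filter rules: keep iff A ≥ A_min, AR ≤ 2, Circ ≥ 0.7 (and optionally: not
touching the tile border). A_min defaults to 1,500 px at 0.12 µm/px — an
equivalent diameter of 5.24 µm, far below the expected 8–15 µm spores —
and `FilterRules.for_scale` re-expresses that physical size at any pixel
scale. The minimum-area reading (rather than maximum) follows the rule's
stated purpose of removing *small* amorphous particles; both directions
are available (`max_area_px`). Border exclusion is available but off in
the default pipeline: clipped slivers at tile edges are almost always
removed by the area/circularity rules, and the near-complete part of a
straddling spore then still yields one record, which keeps counts unbiased
when tiles are processed independently without cross-tile deduplication.

## Distribution analysis

Diameters are analyzed with a Gaussian KDE on a 512-point grid (bandwidth:
0.9·min(sd, IQR/1.349)·n^(−1/5), the classic rule of thumb). Extrema
positions are refined by quadratic sub-grid interpolation. A maximum must
(a) have ≥ 1% relative prominence — KDE micro-ripples are not peaks — and
(b) clear a high-pass threshold that removes rare non-target size classes.
The threshold is specified on a count-proportional frequency-density scale
(default 4 × 10⁻⁶ per count) and converted to the normalized density as
4e-6·n, so its strength grows with sample size exactly as a count-scaled
density plot would show; the analysis interval is delimited by the
outermost crossings of density = threshold. Types: 1 (normal-sized) from
the left limit to the minimal local frequency between the two peaks,
2 (oversized) from that boundary — which itself classifies as Type 2 — to
the right limit, 0/3 outside the interval. Gamma fits are two-parameter
maximum likelihood (no location shift) per type; bimodal samples are split
at the boundary and fitted per side, and the oversized/normal peak-volume
ratio is reported as 1:r with r to two decimals. The MAD across sporocarp
mean diameters excludes Type 2 spores, so it describes the normal-sized
population. Empirical skewness (Fisher–Pearson, bias-corrected) is
reported alongside the gamma-derived 2/√k since either convention appears
in published tables.

## Spatial analysis

Per-tile counts of a diameter class form an R × C lattice. Moran's I uses
queen contiguity, row-standardized, by default (rook available): queen is
the common default for lattice count data, and no published weight matrix
exists to match. Significance is a permutation test — values shuffled
among tiles, the standard randomization null for counts — with the
add-one rule p = (1 + #{I_sim ≥ I_obs})/(1 + n_sims), one-sided for
clustering by default (two-sided available), 25,000 permutations, seeded.
The permutation distribution's mean matches the closed form
E[I] = −1/(n−1), and the implementation agrees with a brute-force double
summation to 10⁻¹² on random small lattices.

## Synthetic data: what it does and does not emulate

The generator renders spores as anti-aliased dark ellipses (area-coverage
shading from the signed distance to the outline, so pixel-count areas
track analytic areas to sub-percent accuracy), with per-object intensity
≈ 30% of max, small per-object and per-channel jitter (exercising the RGB
statistics), axis ratios ≤ 1.05, Gaussian sensor noise (sd 3 intensity
units), and Poisson object counts. Contacts are constructed as tangent
pairs with half-pixel interpenetration so that rasterized masks actually
connect; isolated spores keep ≥ 2 px clearance. Contaminants: capillitium-
like fibers (capsules 25–70 µm long, ~2–3 µm wide), bright-centered air-
bubble rings (22–40 µm outer diameter), and sub-5 µm debris blobs —
placed clear of spores, since overlapping contamination is a slide-
preparation failure outside the generator's scope. Objects straddling a
tile boundary are rendered clipped in both tiles, mimicking unstitched
grids with minimal overlap. Classes can be given a central Gaussian
density hotspot (sd 0.22 of the slide extent, 50/50 mixed with uniform)
to emulate size-dependent transport during mounting for the Moran
contrast.

Not emulated: optics (PSF, depth of field, chromatic aberration),
out-of-focus or stacked spores, wall ornamentation, illumination
gradients, and real capillitium branching. Passing the benchmark therefore
demonstrates the correctness of the measurement chain on well-prepared
monolayers, not robustness to poor preparations — on real slides the QC
stage, not the benchmark, is what guards those failure modes.

## Benchmark problem sizes

The reference benchmark is a 12 × 12 grid of 1,280 × 960 px tiles at
0.5 µm/px — a deliberate desk-scale stand-in for full-resolution scans
that keeps the same object count (≈ 20,000 spores, ~26 px across) while
rendering and processing in about three minutes. It uses the 80/20
bimodal mixture (modes 12.9/15.9 µm), 30% contact fraction, ≈ 5%
contaminants, clustered normal-sized vs. scattered oversized spores, and
the minimum-area rule re-expressed at 0.5 µm/px. Scored against ground
truth (matching radius 0.45 × the equivalent diameter): ≈ 98% of spores
yield exactly one kept record, ≈ 94% of touching pairs separate into two
single records, < 0.5% of isolated spores are falsely split, ≈ 97% of
matched diameters are within 0.25 µm, and contaminant specificity is
≈ 100%; exact values per seed are computed by `scripts/acceptance.py` and
the acceptance tests. The ground-truth diameter of a rendered ellipse is
compared as its equivalent-circle diameter d/√AR.

## Known limitations

* Truly overlapping (stacked) spores are not resolved; they are excluded
  upstream by preparation and BScore, or downstream by the circularity cut
  (a fused pair's circularity ≈ 0.5).
* The eigenvalue calibration assumes the expected modal diameter is
  roughly right (within a factor ~2); wildly wrong `expected_diameter_um`
  misplaces both the junction-link radius and the threshold.
* The high-pass threshold's count-scale default ties peak filtering to
  sample size; for very small samples (n ≲ 1,000) it filters little and
  clipped-fragment shoulders can surface as spurious low-diameter peaks —
  visible in miniature demos, absent at survey scale.
* Ornamented spores measure systematically large in outline mode; ellipse
  mode is preferable there, and neither corrects for ornaments.
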