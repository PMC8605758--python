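# sporemorph

Automated counting and sizing of tens of thousands of quasi-spherical
spores from calibrated brightfield tile scans.

Spore size is a key character in the taxonomy of myxomycetes (plasmodial
slime molds) and other sporulating organisms, but manual measurement tops
out at a few dozen spores per specimen — far too few to resolve the shape
of a size distribution, detect oversized-spore subpopulations, or compare
specimens statistically. `sporemorph` implements the full chain from raw
microscope tiles to distribution statistics for preparations where spores
lie in a monolayer on a bright field:

1. **Tile QC** — per-tile *IScore* (background-intensity consistency,
   a high grayscale percentile as percent of the intensity maximum) and
   *BScore* (mean brightness mapped between "no spores" and "field full of
   spores" anchors; dense tiles score low). Tiles with `BScore < 50` or an
   IScore off the slide median by more than 10% are excluded.
2. **Segmentation** — a scribble-trained random-forest pixel classifier
   (two classes: spore vs. background) over a small filter bank, or an
   automatic-threshold fallback for high-contrast slides.
3. **Separation of touching spores** — where two outlines meet, the
   *smaller* eigenvalue of the structure tensor spikes in the two
   acute-angled corners flanking the contact. Thresholded corner regions
   are paired (nearest first, within 0.6 × the modal spore diameter) and
   joined by one-pixel background-colored lines that cut the pair apart.
4. **Morphometry** — 4-connected labeling and per-object measurement:
   area *A*, perimeter *P*, moment-fitted ellipse axes (*a*, *b*),
   circularity 4π·A/P², aspect ratio a/b, roundness 4A/(π·a²), solidity,
   and per-channel RGB statistics. Non-targets are removed by shape rules
   (minimum area for debris, AR > 2 for capillitium fibers, circularity
   < 0.7 for bubble rings and fused clumps).
5. **Distribution statistics** — kernel density of the equivalent-circle
   diameters, peak/valley detection above a high-pass threshold, spore-type
   classification (Type 1 normal-sized / Type 2 oversized split at the
   between-peak minimum), maximum-likelihood gamma fits per type with the
   gamma mode (k−1)/β as the average-size measure, skewness 2/√k, the
   spherical volume ratio of the two peaks, and the mean absolute deviation
   MAD = (1/n) Σ|xᵢ − x̄| of sporocarp means.
6. **Spatial statistics** — per-tile counts of a diameter class form a
   lattice field tested for clustering with Moran's I
   (queen/rook contiguity, row-standardized) and a Monte-Carlo permutation
   test (default 25,000 shuffles, p = (1 + #{I_sim ≥ I_obs})/(1 + n_sims)).

A first-class synthetic slide generator (`sporemorph.fixtures`) renders
seeded tile grids — anti-aliased dark spores with gamma-distributed
diameters, tangent contacts at a controlled rate, fibers, bubble rings and
debris on a noisy bright background — with exact ground truth, so every
stage is benchmarked without microscope data.

## Worked example

Generate a quarter-scale synthetic slide (6 × 6 tiles of 1,280 × 960 px at
0.5 µm/px, ≈ 5,000 spores: 80% normal-sized around 12.9 µm, 20% oversized
around 15.9 µm, 30% touching a neighbour, ≈ 5% contaminants, normal-sized
spores clustered in a central hotspot) and run the full pipeline:

```python
from sporemorph import benchmark_scene, benchmark_config, make_tile_grid, run_pipeline

scene = benchmark_scene(seed=11, tile_rows=6, tile_cols=6)
grid, truth = make_tile_grid(scene)
result = run_pipeline(grid, benchmark_config(seed=1))

print(result.manifest["stages"])
print([(round(d, 2), round(h, 3)) for d, h in result.extrema.maxima])
for t, r in result.spatial.items():
    print(f"type {t}: I={r.I_obs:.3f}, p={r.p_value:.5f}")
```

prints

```
{'qc': {'tiles': 36, 'kept': 36, 'excluded': 0},
 'morphometry': {'labeled': 5291, 'measured': 5291},
 'filter': {'kept': 4861, 'rejected': 430},
 'distributions': {'n_analyzed': 4861, 'n_maxima': 2}}
[(12.69, 0.499), (15.82, 0.133)]
type 1: I=0.487, p=0.00008
type 2: I=0.089, p=0.10132
```

All 36 tiles pass QC; 5,291 objects are measured, of which 4,861 survive
the shape filters (the rejects are contaminants, clipped edge fragments
and unseparated clumps). The diameter density shows the two generator
modes (12.69 and 15.82 µm found vs. 12.9 and 15.9 µm generated), and the
per-type gamma fits put the peaks at 12.73 and 15.66 µm. Moran's I
recovers the spatial design: the clustered normal-sized spores give a
strongly significant positive I, the uniformly scattered oversized spores
do not.

The same pipeline is scriptable from a shell — `sporemorph simulate`,
`train`, `qc`, `segment`, `measure`, `analyze`, `spatial`, and `run`
(`sporemorph run --tiles <dir> --out <dir> --um-per-px 0.12`) — reading
tile grids named `<sample>_r<row>_c<col>.tif` and writing the object table
CSV, QC report, per-sporocarp summary, spatial report and a manifest with
the seed and config hash.

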