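# Methods

## Problem and model

`tortuosity3d` quantifies how tortuous a cerebral artery is from a labelled
3D segmentation (e.g. Circle-of-Willis arteries segmented from time-of-flight
MR angiography at ~0.625 mm isotropic resolution). The vessel is treated as a
space curve r(s), parametrized by arc length s ∈ [0, L], with curvature

    κ(s) = ‖r′(s) × r″(s)‖ / ‖r′(s)‖³      [mm⁻¹]

and four summary metrics per artery:

| metric | formula | scale behavior | intuition |
|---|---|---|---|
| AOC | L / C (C = endpoint chord) | invariant | elongation of the path |
| κ_m (total curvature) | ∫₀ᴸ κ ds | invariant | accumulated turning |
| κ_ms (mean squared curvature) | (1/L)∫₀ᴸ κ² ds | ∝ 1/a² | emphasizes sharp bends |
| κ_rms | L·√((1/L)∫₀ᴸ κ² ds) | invariant | RMS turning, rescaled by L |

AOC alone is blind to high-frequency low-amplitude "wiggle" (it barely
lengthens the arc), which is exactly the coiling pattern the curvature
metrics capture. κ_rms carries an explicit factor of L so that uniformly
rescaling the vessel leaves it unchanged, mirroring κ_m; the bare RMS
√((1/L)∫κ²ds), which scales as 1/a, is available separately
(`rms_curvature_bare`). For κ_ms the length-averaged form (1/L)∫κ²ds was
chosen; it is not scale invariant under either plausible reading, and the
package documents the chosen normalization explicitly.

All computation is done in world millimetres through the NIfTI affine
(0-based voxel indices, voxel-center convention). The scale-invariant
metrics are unaffected by this choice; κ_ms is reported in mm⁻².

## Pipeline

1. **Binarize** — isolate the target label; an absent label is an error
   naming the label.
2. **Skeletonize** — 3D medial-axis thinning (scikit-image). The mask must
   be one 26-connected component; fragmented masks raise an error listing
   component sizes (an opt-in flag keeps the largest component instead,
   with a warning). Closed loops are an error, not silently cut: the
   arteries of interest are open curves.
3. **Endpoint detection** — a skeleton voxel whose 26-neighborhood contains
   exactly one other foreground voxel is a terminal. With more than two
   endpoints (spurious side branches), the endpoint pair with the maximal
   geodesic distance is used, spurs are dropped, and a warning is recorded
   in the output row.
4. **Path ordering** — traversal of the skeleton's 26-adjacency graph from
   one endpoint to the other (Euclidean-weighted shortest path; for a clean
   two-endpoint skeleton this is the unique walk). The start endpoint is
   the lexicographically smaller voxel index; every metric is
   reversal-invariant, so the choice is cosmetic.
5. **Unit-speed spline fit** — see below.
6. **Metrics + quality** — curvature integrals by the trapezoidal rule on
   512 uniform arc-length samples (doubling the sample count must move no
   metric by more than 0.1%, otherwise a `metric_integration_unstable`
   warning is recorded); RMSE of point-to-curve residuals; the combined
   score RMSE + κ_rms as a single per-vessel quality number.

Batch runs emit one CSV row per (input, label); per-vessel failures become
rows with an error code rather than aborting the batch, since clinical
batches routinely contain a few unusable segmentations.

## Spline fitting

Curvature needs second derivatives, which are hopeless on raw voxel paths
(skeleton steps are quantized to the grid). The estimator is a two-stage
spline fit:

**Stage 1 — penalized smoothing spline.** The ordered points (consecutive
duplicates merged; at least 4 distinct points required) are fit with a
natural cubic smoothing spline in all three coordinates jointly, under
chord-length parametrization. The roughness penalty λ is either given
(`smoothing=value`; 0 interpolates) or selected by generalized
cross-validation pooled across x, y, z (`smoothing="auto"`, the default).
Pooling matters: the pooled residual and roughness are rotation invariant,
so the selected λ — and hence the fitted curve — commutes with rigid
motions. Before fitting, the point list is extended at both ends by
reflection through the endpoints (15% of the point count per side) and the
curve is restricted to the original span afterwards; natural end conditions
force κ → 0 at the spline boundary, and the padding pushes that bias onto
discarded curve. Without padding the end bias costs ~3% of total curvature
even on noiseless phantoms; with it the loss is about 2% (flagged: the
first/last 10% of arc length are marked `interior=False` in the curvature
profile, though metrics integrate the full curve).

An earlier candidate for automatic smoothing — minimizing the combined
score RMSE + κ_rms over a λ grid — was rejected after measurement: the
objective is degenerate at strong smoothing, because flattening a coiled
vessel toward its axis reduces κ_rms faster than the RMSE grows (for a
tight helix the objective actually prefers a straight line). GCV has no
such failure mode and adapts correctly both to additive point noise and to
the ~0.18 mm quantization zigzag of voxel skeletons.

**Stage 2 — arc-length reparametrization.** Cumulative arc length is
computed by composite Simpson quadrature of ‖r′‖ on a dense parameter grid
(4× the resampling density), the curve is resampled at uniform arc length
at 10× the input point count, and an interpolating cubic B-spline is refit
with the arc-length values as parameter. The result satisfies
‖r′(s)‖ = 1 to well below 1% (checked in tests at 1000 points), so the
curvature samples integrate directly over arc length. Curvature still uses
the full formula ‖r′×r″‖/‖r′‖³ rather than the unit-speed shortcut ‖r″‖,
making it robust to the residual speed error.

**RMSE.** Residuals are minimal Euclidean distances from each input point
to the fitted curve: nearest neighbor on a 2048-sample arc-length grid,
refined by three vectorized parabolic-interpolation passes on the squared
distance (ties resolve to the smaller parameter). The refined and
grid distances agree to ~1e-8 on test curves; the grid-only variant
(`refine=False`) is used inside replicate sweeps.

## Phantom generator

Phantoms provide the ground truth that clinical data cannot: a circular
helix (radius r, pitch p, c = p/2π) has constant curvature r/(r²+c²) and
arc length per turn √((2πr)²+p²); circular arcs and straight lines cover
the known-AOC and zero-curvature controls. Sampling is uniform in the helix
angle, which for a helix is uniform in arc length.

Noise is isotropic Gaussian on point coordinates with
σ = amplitude / SNR, where the amplitude is the helix radius (or the RMS
deviation from the centroid for other shapes); the generator stores the
clean ground truth alongside the noisy points and is bit-reproducible for
a fixed seed. Voxelization marks a voxel foreground iff its center lies
within the tube radius of the densified polyline (no partial volume — the
pipeline consumes binary masks), builds a diagonal affine from the
requested spacing, and refuses masks that come out empty or disconnected.

What the phantoms do **not** emulate: MR acquisition physics, intensity
inhomogeneity, segmentation boundary errors, vessel caliber variation, or
branching anatomy. Passing the phantom suite therefore demonstrates the
geometry pipeline (skeleton → spline → metrics) is correct and noise-robust,
not that any particular clinical segmentation is accurate.

## Validation protocol and problem sizes

The shipped acceptance script and test suite recompute, from scratch:

- curvature (±2% over the interior 80%) and arc length (±0.5%) on a clean
  unit helix of 200 points;
- scale invariance: doubling r and p moves AOC, κ_m, κ_rms by <1% and
  divides κ_ms by 4 within 2%;
- monotonicity: κ metrics strictly decrease with pitch
  (π…8π at r=1, 2 turns) and κ_m, κ_rms strictly increase with turns
  (1, 2, 4);
- noise response: 100 seeded replicates per SNR ∈ {2, 5, 10, 50} on a fixed
  2-turn helix; the mean combined score is strictly decreasing in SNR;
- the end-to-end voxel pipeline on a helix tube (r=10 mm, p=10 mm, 2 turns,
  1.5 mm tube radius, 0.625 mm isotropic — the resolution regime of the
  intended segmentations): exactly 2 endpoints, 1 component, all four
  metrics within 5% of closed form. Two turns are used because a single
  turn leaves only ~90 skeleton voxels, where end effects alone push κ_ms
  outside 5% for any smoothing of the quantized path;
- degenerate cases (line, semicircle, closed ring, fragmented mask,
  Y-branch with brute-force path oracle) and invariances (reversal, rigid
  motion at interpolating smoothing, axis flips with affine update at 1e-2
  for voxel-quantized runs; the flip phantom uses a long chord, since a
  one-voxel endpoint shift on a short chord already moves AOC by ~3%).

## Known limitations

- Torsion is not estimated; the metrics are curvature-only.
- Data-driven λ selection is equivariant only up to the flatness of the GCV
  curve; bitwise-critical invariance comparisons should fix λ.
- Very short skeletons (< ~100 voxels) carry end-effect biases of several
  percent in κ_ms; the `interior` flag and the combined quality score are
  the intended guards.
- Skeleton-based centerlines inherit thinning artifacts near structure
  ends (caps can curl the tip); the longest-geodesic endpoint-pair rule
  plus spur warnings make this deterministic but cannot remove the bias.
- Vessels whose true topology is looped or branched beyond simple spurs
  are rejected rather than guessed at; upstream relabelling is the fix.
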