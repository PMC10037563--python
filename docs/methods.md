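# Methods

This note documents the models the package implements, the defaults it
chooses where the underlying study left the design open, what the
synthetic phantom does and does not emulate, and the numerical choices
that matter for reproducing its results.

## Coordinate and data conventions

Arrays are indexed `(i, j, k) ↔ (x, y, z)` with z the tibia long axis
(axial-slice stacking direction).  Volumes are exchanged as MetaImage
(`.mhd` header + `.raw` payload, little-endian, uncompressed) through
SimpleITK; complex multi-echo volumes are stored as paired
`*_real.mhd`/`*_imag.mhd` files because MetaImage has no complex
element type.  All acquisitions of a session share one grid; manifests
are validated against that invariant.

## ADC

Directional ADC is the two-point log ratio `(1/b_j)·ln(S_b0/S_bj)` in
mm²/s, reported ×10³ as µm²/ms; the isotropic map is the arithmetic
mean over the three diffusion axes, and the trace DWI the voxelwise
geometric mean.  Two exclusion rules run before any logarithm: a pixel
must retain at least 20% of the mean diffusion-weighted signal and must
not be brighter at b = 3000 than at b = 0 (which would imply negative
ADC).  Open choices resolved here:

* The reference region for the 20% rule is the foreground (VOI dilated
  by 2 voxels), recomputed per direction.  A body-wide mean would be
  dominated by empty background in synthetic volumes.
* Exclusions are pooled across directions (logical AND), so the
  isotropic average always uses exactly three directions.
* Per-axis b-values are manifest inputs (default 3000 s/mm² each).

## Water–fat decomposition (PDFF)

The four 3-echo gradient-echo series (first TEs 1.476, 1.793, 2.110,
2.427 ms; intra-series spacing 2.174 ms; gains constant) are pooled and
sorted into a 12-echo train.  Note the sorted train is *interleaved*,
not uniformly spaced: within each group of four first/second/third
echoes the offsets are 0.317 ms, but the jump between echo groups is
1.223 ms.  Nothing downstream assumes uniform spacing — the W/F design
matrix is built from the actual TE list — so the merge validates only
monotonicity and uniqueness.

Per voxel the signal model is
`s(TE) = (W + F·Σ_p α_p·e^{i2πf_p TE})·e^{i2πψTE}`, complex W and F,
with a seven-peak triglyceride spectrum at shifts 0.90, 1.30, 1.60,
2.02, 2.24, 2.75, 4.20 ppm (water at 4.70 ppm, converted to Hz at the
300 MHz proton frequency) and relative amplitudes 0.088, 0.642, 0.058,
0.062, 0.058, 0.006, 0.086 normalized to 1 — a standard multi-peak
marrow/liver parameterization, fully configurable via JSON.

Field-map estimation follows the discretize-then-smooth paradigm:

1. The variable-projection residual `‖(I − A·pinv(A))·D(ψ)·s‖²` is
   evaluated on a candidate grid (default ±600 Hz; API default step
   2 Hz; the study pipeline uses 10 Hz, see below).
2. The labeling minimizing `Σ_v residual(ψ_v) + λ·Σ_{uv} |ψ_v − ψ_u|`
   over 6-neighbor pairs inside the mask is computed by a *single
   min-cut* on a layered (Ishikawa-style) graph.  Because the pairwise
   term is convex in the label difference, this is the exact global
   optimum — strictly stronger than iterated move-making.  Capacities
   are scaled to int64 with ~1e-9 relative rounding;
   `scipy.sparse.csgraph.maximum_flow` solves the cut, and labels are
   read off the source-side reachability of the residual graph.  Exact
   chain dynamic programming and exhaustive enumeration on tiny
   instances serve as independent oracles in the tests.
3. Optional continuous refinement polishes each voxel's ψ by bounded
   golden-section search within ±1 grid step, removing the grid
   quantization on smooth fields (machine-precision recovery on
   noise-free data).

The smoothness weight is data-scaled: the cost per grid step of
neighbor disagreement is `smoothness_weight ×` the median per-voxel
residual range, default factor 0.05.  This default suits smooth fields;
a genuine field discontinuity survives smaller factors (~0.005), which
is what the two-region tests use.  The production pipeline runs a
10 Hz step with refinement enabled: an exact cut at 2 Hz granularity
costs 5× the graph size yet still quantizes ψ, whereas the coarse exact
cut plus local refinement reaches continuous precision in ~1 s for a
~3,000-voxel VOI.

Given ψ, the linear least-squares solve yields complex W, F; magnitudes
are reported and `PDFF = 100·|F|/(|W|+|F|)` (in [0, 100] by
construction, zero and invalid where |W|+|F| = 0).  R2* damping is not
co-estimated by default, matching the minimal W/F/ψ model; the phantom
correspondingly defaults to R2* = 0 (configurable).

Visual screening of decomposition artifacts is replaced by an automated
proxy: a section is flagged when the median absolute neighbor ψ
difference exceeds 20 Hz (checkerboard/swap signature) or when more
than 20% of voxels keep a relative fit residual above 0.25; a manual
(QIB, section) exclusion list covers anything the proxy misses.

## MTR

`MTR = (MToff − MTon)/MToff` on pixels whose MToff SNR exceeds 20;
below-threshold pixels are zeroed and flagged invalid.  The gate uses
MToff — the unsaturated denominator whose instability the gate exists
to protect — and negative MTR on valid pixels is kept, not clipped, so
section means stay unbiased.  Noise σ is the robust SD (1.4826·MAD) of
a signal-free background region divided by 0.655, undoing the Rayleigh
compression of magnitude noise.  When a pipeline input is genuinely
noise-free (estimated σ = 0), a nominal σ of 1e-12×max signal keeps the
gate defined with every signal pixel valid.

## Sections and QC

The axial slice with the largest in-VOI pixel count anchors z = 0 (ties
break to the smallest index); a voxel joins a section when its
slice-center distance, measured distally, falls inclusively within
S1 1.8–9.0 mm, S2 9.8–11.7 mm, S3 12.6–13.5 mm (a 1 µm tolerance
absorbs float slice arithmetic).  The 9.0–9.8 and 11.7–12.6 mm gaps are
guard bands and belong to no section.  A coarser span variant
(2–9 / 10–12 / 12.5–13.5 mm) is accepted as a configuration override.
Section QC eliminates ADC means < 0.05 µm²/ms and MTR means < 0.1
(strict inequalities), PDFF sections flagged by the artifact proxy or
the manual list, and sections with no valid pixels; QC is idempotent.

## Repeatability

With paired differences d = retest − test, the within-subject SD is the
RMS form `wSD = sqrt(Σd²/2N)` — the standard paired-replicate
estimator, consistent with RC = 2.77·wSD and with the Bland–Altman
limits (LOA half-width / RC → 1.96·√2/2.77 ≈ 1.0007).  A literal
"average standard deviation" reading, `mean(|d|)/√2`, is available
behind `estimator="mean_abs"` and flagged in the output; it is biased
low under Gaussian noise.  The chi-square CI uses df = N by default
(each pair contributes one difference) with df = N−1 selectable; both
reproduce report-style CIs only within the rounding of the printed
wSD, and the convention used is recorded in every result.  Bias is
mean(d) (retest minus test), LOA = bias ± 1.96·SD(d) with the n−1
denominator.  Report tables round ADC to 3 decimals, PDFF to 1 and MTR
to 2, while machine output always keeps full precision.

## Trends

Changes are two-sided: |Δ| > RC (strict) ⇒ significant, even though
most observed deltas are one-signed, because the 95%-confidence
threshold is magnitude-based.  The wild-type reference is a two-level
average (within animal, then across animals) so unequal scan counts do
not skew it, with an OLS slope p-value reported per stratum purely as a
time-independence diagnostic.  Baseline references are each animal's
earliest QC-passing scan at/after week 5 for ADC (no b = 3000
acquisition existed at weeks 3–4) and week 3 for PDFF and MTR; with
several scans in the window the earlier one wins, deterministically.
The wild-type comparison reuses the section-specific RC estimated from
diseased test–retest pairs — the only RC available, as wild-type pairs
were too few.  Cohort counts divide significant by defined records; the
majority marker requires the numerator to strictly exceed half the
denominator.

## The synthetic phantom

Geometry: 64³ voxels at 0.1×0.1×0.3 mm (z covers 18.9 mm ≥ the 13.5 mm
section span), a 0.8 mm-diameter marrow tube (murine tibia marrow is
<1 mm across) with a wider bulge at slice 10 anchoring the section
origin.  Truth fields vary only along z: constant inside each section
span — so section-mask means equal the requested table values exactly —
and linearly interpolated across the guard bands.  The B0 truth is a
low-order 3D polynomial scaled to a configurable peak amplitude
(default 20 Hz, a plausible small-animal shim residual; the estimation
grid extends to ±600 Hz).

Forward models: DWI `S = S0·e^{−b·ADC·10⁻³}` with Rician noise per
volume; MGE from the same multi-peak model the fit uses, with complex
Gaussian noise; MT-off/on with `MTon = MToff·(1 − MTR)`, optional
linear distal coil falloff, and Rician noise.  Default noise levels are
zero (recovery conditions); noisy tests use baseline SNR ≥ 50.

Test–retest pairs and longitudinal cohorts are generated at the
*section-value* level: each session's section truth is the animal value
plus N(0, wSD²), so SD(RT − TT) = √2·wSD and the repeatability module's
recovery target is exact by construction; voxel noise adds on top when
volumes are rendered.  Cohort defaults are the measured study
conditions: wild-type section means and SDs, diseased trajectories at
window-midpoint weeks 3.5–13.5 with their between-animal SDs (drawn
once per animal as an additive offset), and the per-stratum
within-subject SDs.  Seeding is hierarchical (`SeedSequence.spawn` per
animal), so identical seeds give identical cohorts.

What the phantom does not emulate — and hence what passing tests do not
establish about real data: cortical bone and partial-volume effects at
the endosteal border, motion/ghosting, eddy-current phase errors,
R2*-induced PDFF bias, spatially varying noise, within-section texture,
and segmentation variability (the VOI is exact).  Recovery results
certify the *inverse problems and statistics*, not acquisition physics.

### The qualitative trend-pattern check

The starred-majority reproduction (mid-tibia S2 majority-significant by
weeks 9–10 across all three biomarkers; no S1 PDFF majority at weeks
5–6) is run with visit-level wSD at 1% of the measured values.  This is
deliberate: the S2 ADC trajectory delta at weeks 9–10 (0.090) clears
its RC (0.087) by only 0.003 — about a tenth of the measured wSD — so
at realistic noise the per-animal exceedance is a coin flip and the
check would measure seed luck, not trajectory geometry.  Shrinking the
visit noise isolates what the check is for: that the published cohort
trajectories, compared against the published RC thresholds through the
package's baseline/counting logic, produce the published qualitative
pattern.

## Problem sizes and determinism

The test suite runs the full 64³ end-to-end recovery (a few seconds),
200-replication estimator recovery, and 10⁴-pair consistency checks;
all stochastic tests fix seeds and the whole suite completes in well
under a minute on one CPU.  The min-cut solver is deterministic;
argmax/argmin ties resolve to the smallest index throughout.

## Known limitations

* The field-map candidate range (±600 Hz) does not cover water–fat
  swap aliases at 7 T (~±1020 Hz); swaps manifest as residual/roughness
  flags rather than as alternative labelings.
* R2* is neither simulated nor fitted by default; marrow with short T2*
  would bias PDFF in ways the phantom does not exercise.
* The chi-square CI convention (df = N vs N−1) is genuinely ambiguous
  in the source material; both are implemented and labeled.
* `mean_abs` wSD is provided for comparison only and is not used in any
  reported statistic.
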