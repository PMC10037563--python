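# marrowqib

Quantitative MRI biomarkers of murine tibia bone marrow: biomarker map
generation (ADC, PDFF, MTR), bone-marrow section parsing with quality
control, test–retest repeatability statistics (wSD / RC / Bland–Altman),
and RC-thresholded longitudinal change-trend analysis — validated
end-to-end on a synthetic multi-contrast phantom.

## The problem

Bone-marrow biopsy is the only routine readout of myelofibrosis, and it
samples millimeters of tissue from one site.  Quantitative MRI offers
noninvasive alternatives: the apparent diffusion coefficient (ADC)
tracks cellularity, the proton density fat fraction (PDFF) tracks
marrow adiposity, and the magnetization transfer ratio (MTR) tracks
macromolecular content such as fibrosis.  Whether a longitudinal change
in any of these is *real* depends on measurement precision: the
repeatability coefficient RC = 2.77·wSD — derived from consecutive-day
test–retest scans — is the smallest change between two measurements
significant with 95% confidence.  This package implements the full
analysis chain for murine tibia bone marrow and, because the underlying
animal data are not publicly deposited, ships a synthetic phantom
generator whose defaults reproduce the study conditions (section means,
longitudinal trajectories, within-subject SDs) so every stage can be
validated against known truth.

## The models

* **ADC** (µm²/ms), per direction j from b = 0 and b ≈ 3000 s/mm²:
  `ADC_j = (1/b_j)·ln(S_b0/S_bj)`, isotropic ADC = mean over X, Y, Z;
  trace DWI = geometric mean of the three directional DWIs.  Pixels
  with `S_b3000 < 0.2·mean(S_b3000)` or `S_b0 < S_b3000` are excluded.
* **PDFF** (%): four 3-echo complex gradient-echo series with staggered
  first TEs merged into a 12-echo train; per voxel
  `s(TE) = (W + F·Σ_p α_p e^{i2πf_p TE})·e^{i2πψTE}` with a seven-peak
  fat spectrum.  The field map ψ is estimated by discretizing
  candidates and minimizing `Σ residual(ψ_v) + λ·Σ|ψ_v − ψ_u|` with a
  single exact min-cut (convex pairwise term), then the linear W/F
  solve gives `PDFF = 100·|F|/(|W|+|F|)`.
* **MTR** (dimensionless): `(MToff − MTon)/MToff` on pixels with
  MToff SNR > 20.
* **Sections** S1/S2/S3: z-spans 1.8–9.0, 9.8–11.7 and 12.6–13.5 mm
  measured distally from the widest axial VOI slice; section means of
  ADC < 0.05 µm²/ms or MTR < 0.1 are automatically eliminated.
* **Repeatability**, from paired differences d = RT − TT:
  `wSD = sqrt(Σd²/2N)`, `RC = 2.77·wSD`, chi-square CI on wSD,
  Bland–Altman bias ± 1.96·SD(d).
* **Trends**: per animal and section, Δ versus a wild-type collective
  average or the animal's own baseline scan; |Δ| > RC ⇒ significant;
  cohort tables report `#(>RC)/total` with a majority marker.

## Worked example

```sh
python examples/04_repeatability.py
```

simulates 27 test–retest pairs of the mid-tibia PDFF stratum with an
injected within-subject SD of 5.58% and prints:

```
N pairs        : 27
stratum mean   :  20.36 %
bias (RT-TT)   :  +1.20 %
wSD  (95% CI)  :  4.90 (3.87, 6.67) %
RC   (95% CI)  : 13.57 (10.73, 18.48) %
LOA            : (-12.43, +14.84) %
```

The estimated wSD (4.90%) sits near the injected 5.58% (a 27-pair
estimate carries ~14% sampling error, which the CI reflects), RC is
exactly 2.77×wSD, and the Bland–Altman limits of agreement bracket the
bias.  A PDFF change larger than ~14–15% between two scans of the same
animal would therefore be significant at 95% confidence.

The other examples cover the remaining capabilities: phantom synthesis
(`01`), map generation with exact noise-free recovery (`02`), section
parsing and QC (`03`), and longitudinal trend counting (`05`, which
shows the dynamic mid-tibia S2 section turning majority-significant
across all three biomarkers by weeks 9–10, four weeks after baseline).

A thin CLI wraps the same functions:

```sh
marrowqib simulate --seed 17 --out-dir sim/
marrowqib maps --manifest sim/manifest.json --out-dir maps/
marrowqib repeatability --pairs pairs.csv --out repeatability.csv
```

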