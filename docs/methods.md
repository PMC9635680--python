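# Methods

## The overlap index

For two serial SUVR volumes on one voxel grid and an ROI mask, the pipeline
is: restrict to the ROI → keep finite voxels with SUVR strictly above the
intensity threshold (default 1.4) → label connected clusters under
18-connectivity → discard clusters with fewer than `min_cluster_voxels`
voxels (default 20; a cluster of exactly 20 survives) → multiply the two
cleaned masks. Then

- `OI = N_overlap / N_b`, the fraction of cleaned baseline voxels that
  remain supra-threshold at follow-up;
- `overlap size = N_overlap / N_ROI`;
- Dice `2·N_overlap/(N_b+N_f)` and Jaccard `N_overlap/|union|` are
  reported alongside as the symmetric comparators.

Connectivity definitions (6 = faces, 18 = faces+edges, 26 = all 3×3×3
neighbors) use `scipy.ndimage.label` structuring elements; the test suite
cross-checks the resulting partitions against an independent brute-force
flood fill on hundreds of random small masks.

Documented conventions where the procedure admits choices:

- **Threshold strictness.** Voxels must be strictly greater than the
  threshold, mirroring the strict "more than" convention of the
  abnormality cutoffs; a `strict_threshold` switch admits ≥.
- **N_b is counted after cluster filtering** (switchable via
  `count_before_filter`). Counting before filtering would let discarded
  noise voxels deflate OI.
- **The overlap set itself is never size-filtered** — only the per-scan
  masks are; the overlap is their plain product.
- **Cluster filtering happens inside the ROI only.** Supra-threshold
  voxels outside the ROI cannot rescue a small in-ROI cluster across the
  size filter (OI is defined per ROI/meta-ROI).
- **Empty baseline mask ⇒ OI undefined**, reported with a reason code
  (`empty_baseline` / `empty_both`) rather than 0: "nothing to persist" is
  semantically different from "signal vanished". Cohort statistics exclude
  undefined pairs and report the count; coding them as 0 would bias
  low-SUVR groups downward.
- Series of more than two scans are handled as consecutive pairs
  (1–2, 2–3, …).

## SUVR stack

- Normalization divides every voxel by the median raw uptake over the
  reference mask (cerebellar crus); scale-equivariant by construction.
- Regional SUVR is the median over ROI voxels, excluding CSF-segmented and
  non-finite voxels. Even-count medians use the mean of the two middle
  order statistics. A missing CSF mask is logged, not an error.
- The tau meta-ROI (amygdala, entorhinal, fusiform, parahippocampal,
  inferior temporal, middle temporal; bilateral regions pooled as one via
  multi-id lookup-table entries) is the unweighted mean of the regional
  medians. The amyloid composite is the voxel-number-weighted mean over
  seven cortical regions.
- Abnormality: tau SUVR > 1.29, amyloid SUVR > 1.42, strict.
- ΔSUVR = (follow-up − baseline) / (interval/365.25) per year.

Grid compatibility (shape, spacing, orientation within 1e-3 mm) is a hard
precondition for every metric; volumes are canonicalized to RAS axis order
on load and never resampled, since resampling would alter cluster topology.

## Phantom model

Each scan is `background (1.0) + persistent lesions(t) + transient
artifacts + N(0, noise_sd)` on a 48×48×10 voxel grid (2 mm spacing)
holding a 4×4 block layout of 14 bilateral regions: the six meta-ROI
regions, the seven amyloid-composite regions, and a cerebellar-crus
reference block that receives background + noise only. The lowest z-slice
of every non-reference region is flagged CSF and fixed at SUVR 0.3, so CSF
exclusion in regional medians is exercised for real.

- **Lesions** are axis-aligned ellipsoids with hard edges; at time `t`
  (years) the radii grow by `growth_rate·t` voxels and the amplitude by
  `amplitude_rate·t` SUVR. Non-persistent lesions appear in exactly one
  scan. An optional Gaussian-smoothed noise switch
  (`noise_smooth_sigma`) produces spatially correlated noise, since
  reconstructed PET noise is correlated; the default is white noise, the
  simplest model consistent with the premise that noise does not repeat
  spatially.
- **Artifacts** are fresh per scan: Poisson(`artifact_rate`, default 2)
  ellipsoids of amplitude 0.6 placed uniformly over non-reference,
  non-CSF labeled voxels, with radii drawn so cluster sizes straddle the
  20-voxel filter boundary — they stress exactly the mechanism OI relies
  on.
- **Noise scale.** `noise_sd = 0.1` SUVR. The supra-threshold margin of
  the background (0.4) then makes isolated noise crossings rare while the
  induced fluctuation of regional medians stays in the few-0.01 range,
  matching the reported scale of test–retest SUVR variability (up to
  ~0.05).
- **Cohort groups.** Lesion subjects carry one ellipsoid (radii
  6.5×6.5×5.0 voxels) covering ~90 % of the entorhinal stand-in block:
  a regional *median* only responds when more than half the region is
  covered, so meta-SUVR and ΔSUVR track lesion amplitude. Baseline
  amplitude is 0.55 ± 0.12 (uniform per subject), keeping every lesion
  supra-threshold in the noiseless limit while spreading the per-voxel
  persistence probability — this across-subject spread is what makes the
  pair 1–2 vs pair 2–3 reliability correlation informative. Accumulators
  add `amplitude_rate = 0.05` SUVR/y (the reported annual-change scale in
  impaired groups) and `growth_rate = 0.3` voxels/y. Scan times default
  to 0 and 1.5 y.
- **Determinism.** All draws descend from one master seed through
  `SeedSequence` spawn keys (per subject) and per-scan substreams; equal
  seeds give bit-identical cohorts, and per-subject seeds stay below 2³¹.
- The manifest attaches synthetic clinical labels per group (noise-only →
  CU A−, stable lesion → CU A+, accumulator → MCI A+). This is a
  labeling convention so the cohort layer runs end to end, not a model of
  diagnosis.

What the phantom does *not* emulate: PET physics (attenuation, scatter,
reconstruction point-spread), anatomical realism, off-target binding
structures (choroid plexus, meninges), perfusion effects, and partial-
volume effects beyond the optional smoothed-noise switch. Passing tests on
phantoms therefore demonstrate the metric's behaviour under its own noise
model — persistent signal vs non-repeating noise — not clinical
performance on real scans.

## Cohort layer

Consecutive scan pairs carry OI, annualized ΔSUVR, interval, and a
progression category from {CUA− to CUA−, CUA− to CUA+, CUA+ to CUA+, CU to
MCI/AD, MCI to MCI, MCI to AD, AD to AD}; reversions and unlisted
transitions map to `other` and are excluded from the standard comparisons.
Amyloid status is required only for CU→CU pairs. Baseline meta-SUVR bins
are half-open: low < 1.29 ≤ mid < 1.5 ≤ high, and the OI split assigns the
boundary 0.5 to `high`; real-valued ties are practically impossible, but
tests need the boundary to be deterministic. By default all pairs of a
multi-pair subject enter group comparisons (flagged in the report), since
the alternative — one pair per subject — discards information; both are
supported by filtering the tidy pair table.

Group comparisons: Kruskal–Wallis omnibus (tie-corrected; the statistic is
defined as 0 when all observations are identical) followed by Dunn's post
hoc pairwise z-tests on the pooled ranking with the tie-corrected rank
variance. For two tie-free groups Dunn's z reduces exactly to the normal
rank-sum z, which the tests exploit as an independent oracle. Pairwise
p-values are Holm-adjusted by default (Bonferroni and none available);
the adjustment behind "post hoc Dunn" is a genuinely open choice and Holm
is uniformly more powerful than Bonferroni at the same error control.
Linear associations are OLS fits reporting slope, intercept, R² and the
slope p-value.

## Problem sizes

The acceptance script and tests use 100 subjects per group for the
discrimination analyses, 50 per group for the ΔSUVR-direction and
reliability analyses, and 1000 replicates for null calibration of the
omnibus test, all on the 48×48×10 default grid — sizes at which every
reported quantity is stable to well within the margins being asserted.

## Known limitations

- The intensity threshold 1.4 is a global constant; per-region or
  per-voxel adaptive thresholds are out of scope.
- OI from a single dynamic scan split in two is not implemented.
- Partial-volume-corrected SUVR variants and cognitive-domain score
  construction are out of scope.
- The phantom's hard-edged lesions make the noiseless OI exactly 1;
  real lesions have graded boundaries, so empirical OI ceilings below 1
  are expected on real data.
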