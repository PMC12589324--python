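# Methods

This note documents the models, conventions and parameter choices behind
`petirae`, in the order the pipeline applies them, followed by the synthetic
data model and the numerical edge-case rules.

## Imaging model

Volumes are axis-aligned 3D scalar grids described by a millimetre spacing
and an origin (the physical coordinate of the centre of voxel `(0,0,0)`).
No rotation component is modelled: the package assumes the PET and CT of one
examination are co-registered and share a physical frame, as is the case for
hybrid PET/CT acquisitions, and all geometric reasoning runs through
spacing/origin rather than voxel counts.  NIfTI-1 is the on-disk format
(the lingua franca of segmentation tooling); spacing is read from the affine
column norms and the origin from its translation.  Modality and units (CT↔HU,
PET↔Bq/mL or SUV) are carried explicitly and checked at every interface.

**SUV convention.**  Body-weight SUV with decay correction of the injected
dose to scan time:

    SUV = C · W_g / (D_Bq · 2^(−t / T½)),   T½ = 109.77 min (F-18)

with tissue density taken as 1 g/mL so Bq/mL and Bq/g interchange.  This is
the universal clinical default; lean-body-mass variants (SUL) are out of
scope.  Acquisition metadata (dose in MBq, weight in kg, uptake time in
minutes) travels as a JSON sidecar per PET volume.  The conversion is linear
in activity and maps a uniform concentration of `D_decayed/W` to SUV 1.0
exactly — both properties are tested.

## Mask preparation

Order of operations (configurable, default): **transfer → erode → remove
lesions**.

- **Transfer** (CT grid → PET grid): nearest-neighbor assignment by physical
  voxel centre.  Nearest-neighbor rather than linear interpolation preserves
  binary labels.  Exact half-way points round up (`floor(x + 0.5)`), a fixed
  tie rule shared with the brute-force test oracle so the two agree
  bit-for-bit.  Target voxels whose nearest source centre falls outside the
  source array are background.
- **Erosion by a physical margin** (default 4 mm): a voxel survives iff its
  Euclidean distance to the nearest background voxel centre — computed in mm
  with the grid's anisotropic spacing via a Euclidean distance transform —
  is *strictly* greater than the radius.  A voxel-count structuring element
  would shrink anisotropic grids by different physical amounts per axis and
  is deliberately not offered.  Voxels beyond the array border are not
  treated as background.  The margin absorbs segmentation error and
  co-registration artifacts at the organ boundary, at the cost of erasing
  very small structures: organs that come out empty (adrenals or thyroid can
  vanish under a 4 mm margin in small subjects) produce flagged missing
  measurements rather than errors, and are excluded from that organ's
  paired analysis only.
- **Lesion removal**: voxelwise subtraction of the lesion-union mask
  (`organ AND NOT lesions`).  An optional metric safety margin around the
  lesions is exposed but defaults to 0 — the minimal reading of removing the
  lesion itself.  Component-level removal (deleting whole connected lesion
  components that touch an organ) is a conceivable alternative but is not
  implemented as the default semantics.

Segmentation itself is *not* part of the package: organ and lesion masks are
pipeline inputs (one binary NIfTI per structure), the adapter pattern for
external deep-learning segmentation tools.

## Quantification

SUVmax is the maximum and SUVmean the plain arithmetic mean (no
partial-volume weighting) of the SUV field over the prepared mask.  The
spleen-to-liver ratio divides spleen SUVmean by liver SUVmean per
patient-timepoint.  Δ is **post − pre**: positive values are uptake
increases after therapy.

## Statistical battery

- **Paired pre/post**: Shapiro–Wilk on the paired differences at
  α = 0.05 — the differences are the quantity the paired t-test assumes
  normal.  Not rejected → paired t; rejected → two-sided Wilcoxon
  signed-rank.
- **Two-group**: Shapiro–Wilk per group; both pass → Student's
  equal-variance t (the scipy default the analysis mirrors); otherwise
  two-sided Mann–Whitney U.
- **2×2 categorical**: Fisher's exact (two-sided) when any expected cell
  count is < 5, else chi-square (with Yates continuity correction, the
  scipy default for 2×2).  The branch taken is always recorded; an explicit
  override is available.  Larger r×c tables use the chi-square test of
  independence.
- **Odds ratio**: the sample estimate (a·d)/(b·c), with the
  Haldane–Anscombe +0.5 correction applied to all four cells only when a
  zero in b or c would make the ratio undefined (a zero in a or d gives a
  well-defined OR of 0).  The conditional-MLE estimator (the one underlying
  Fisher's exact framework) is available via `or_estimator`; the two can
  differ noticeably for sparse tables, so the estimator used is always part
  of the result.
- **Median split**: patients with Δ strictly above the cohort median form
  the "increased" group; ties fall in the non-increased half and the tie
  count is reported.  A Δ > 0 split is available via config as the
  alternative reading of "increased".
- **Laboratory values** (fT3/fT4): complete-case paired analysis; the
  reported n is the number of complete pairs.

P-values are raw — the analysis is exploratory and makes no family-wise
claim.  A Benjamini–Hochberg-adjusted column can be switched on
(`fdr_adjust`), applied per report section.

The gate α (0.05), split statistic, split rule, and OR estimator are all
surfaced in the run config and serialized into the report header, so a
report is reproducible from its own metadata.

## Synthetic data model

Two generators share one effect model.

**Tabular cohort** (default n = 64): adverse-event labels are drawn
hierarchically — thyroid-related composite at 11/64, subtype conditional on
the composite (hypothyroidism 6/11, hyperthyroidism 4/11, thyroiditis 1/11,
mutually exclusive), hepatitis 3/64 and colitis 4/64 independent; "none"
means no event at all.  Per organ, pre-treatment SUVmax/SUVmean and
label-conditional deltas are normal draws:

| quantity | no event | thyroid-related event | hypothyroidism |
|---|---|---|---|
| thyroid ΔSUVmax | N(0.08, 1.12²) | N(2.09, 1.54²) | N(2.12, 0.71²) |
| thyroid ΔSUVmean | N(0.07, 0.56²) | N(0.91, 0.90²) | N(1.04, 0.59²) |

Thyroid pre values: SUVmax N(3.06, 1.09²), SUVmean N(1.85, 0.65²).  The six
other organs are simulated as null (zero-mean deltas with the no-event SDs)
around typical cohort medians (myocardium 7.72/2.37, pancreas 3.41/1.58,
liver 5.17/2.33, hip bone 3.86/1.17, adrenals 2.50/1.78); their pre-value
SDs are set to a 30% CV since only central values are available.  Spleen
baselines (SUVmax 2.6, SUVmean 1.9, giving a spleen-to-liver SUVmean ratio
near 0.8) are typical physiologic values chosen here.  Within a
patient-organ, the SUVmax and SUVmean draws are correlated (ρ = 0.8,
marginals preserved exactly): the two statistics move together in real
scans, and the correlation keeps max ≥ mean in ~95% of rows without
distorting the marginal models.  The remaining inversions are a known
artifact of modelling two coupled statistics by their marginals; the
analyses never compare max to mean within a row.  Cohort-level SDs are used
as patient-level SDs — a modelling choice, since patient-level variance
components are not separately identifiable from cohort summaries.  fT4 is
measured in 27/64 patients (pre N(1.2, 0.3²) ng/dL, shift N(−0.12, 0.59²)),
fT3 in 21/64 (pre N(3.0, 0.5²) pg/mL, shift N(−0.81, 1.31²)).  Age
N(68, 14.4²) clipped to [18, 95]; scan interval exponential with mean 4.5
months (SD ≈ mean, matching the dispersion of real re-staging intervals),
floored at 0.5.

**Image phantom**: a 160 mm cube, CT grid 80³ at 2 mm, PET grid 40³ at 4 mm,
seven non-overlapping ellipsoidal organs with the baselines above, one 6 mm
spherical lesion of SUV 8 in the liver, background SUV 0.5, additive
Gaussian noise (default SD 0.1 SUV, clipped at 0).  The CT renders one
distinct HU value per organ.  Post-treatment images shift each organ by a
per-patient injected Δ drawn from the same label-conditional model (as a
SUVmean shift, with SUVmax co-shifting through the image).  Analytic
geometry makes construction oracles possible: with zero noise and margin 0
the quantified thyroid SUVmean equals its configured baseline exactly, and
the grids are aligned so that CT→PET mask transfer reproduces the PET-grid
rendering bit-for-bit.  PET volumes are written to disk as activity
concentration (Bq/mL) with per-scan acquisition sidecars, so the image path
exercises the SUV conversion.

What the phantom does **not** model: scanner point-spread/partial-volume
effects, attenuation/reconstruction artifacts, physiological uptake
heterogeneity within organs, respiratory motion, or imperfect
co-registration.  Passing tests therefore demonstrate correctness of the
quantification and statistics given adequate masks — not robustness to
segmentation failure or scanner physics, which require real data.

## Numerical choices and edge cases

- Resampling tie rule: half-up (`floor(x + 0.5)`); erosion threshold:
  strict inequality.  Both fixed for reproducibility and mirrored in the
  test oracles.
- Zero-variance difference vectors (all-zero, or constant nonzero) are
  flagged degenerate with no p-value: Shapiro–Wilk is undefined on constant
  input and no location test is meaningful there.  Constant input likewise
  counts as a normality rejection when only one group is constant.
- Degenerate 2×2 tables (an empty margin) return p = 1 with a degenerate
  flag instead of raising.
- Simulated SUV values are truncated below at 0.05 (images at 0); at the
  configured baselines the truncation essentially never binds.
- All randomness flows through one seeded `numpy.random.Generator` per
  entry point; per-patient substreams are derived from it, and identical
  seeds give byte-identical CSV/JSON outputs (floats are written with a
  fixed `%.9g` format).  NIfTI `.nii.gz` files are not byte-compared across
  runs because gzip embeds timestamps.

## Problem sizes used in the test suite and acceptance script

Brute-force oracle checks run on 50 random masks up to 32³ voxels with
random anisotropic spacings (erosion) and 20 random grid pairs (transfer);
Fisher's exact p is compared with exact integer hypergeometric enumeration
on every 2×2 table with total ≤ 40; gated-test p-values are compared with
R's `stats` package to 1e-8.  Calibration uses 1000 null replicates (the
acceptance script reports 500), power 200 replicates at the default effect
model, specificity 50 replicate cohorts of n = 64, parameter recovery one
cohort of n = 10 000, and the end-to-end image path 4–8 phantom patients.
These sizes keep the whole suite in the low minutes while leaving every
rate estimate well inside useful binomial error bars.

## Known limitations

- The grid model is axis-aligned; obliquely acquired volumes would need
  resampling upstream.
- Lesion exclusion is voxelwise; a lesion mask that under-segments a hot
  lesion leaves residual malignant uptake in the organ statistic.
- The printed odds ratio of a sparse median-split table is volatile across
  cohorts (and sensitive to the estimator); the package reports the table
  itself alongside the OR for that reason.
- The generator draws measurement-level values directly for the tabular
  path; it does not model longitudinal within-patient correlation of pre
  and post values beyond the injected shift.
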