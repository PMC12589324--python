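# petirae

Opportunistic organ-level [¹⁸F]FDG PET/CT uptake quantification for
immune-checkpoint-inhibitor (ICI) adverse-event screening.

## The problem

ICI therapy (anti-PD-1, anti-PD-L1, anti-CTLA-4) frequently causes
immune-related adverse events (irAEs) — off-target inflammation of the
thyroid, liver, colon and other organs.  Because FDG uptake tracks
inflammatory glucose metabolism, the PET/CT scans these patients already
receive for tumor staging contain a free, organ-level inflammation signal.
`petirae` implements the quantitative analysis chain that extracts it:

1. **Mask transfer** — organ masks delineated on the CT grid (by an external
   segmentation tool) are transferred to the co-registered PET grid by
   nearest-neighbor assignment of physical voxel centres.
2. **Metric erosion** — each organ mask is shrunk by a physical safety
   margin (default 4 mm), computed with the grid's anisotropic spacing via a
   Euclidean distance transform, to absorb segmentation and co-registration
   inaccuracies.
3. **Lesion exclusion** — tumor-lesion voxels (from an external lesion
   segmentation) are excised from the organ masks so malignant uptake does
   not contaminate organ statistics.
4. **SUV quantification** — per organ and timepoint, SUVmax and SUVmean of
   the body-weight standardized uptake value
   `SUV = C · W / (D · 2^(−t/T½))` (activity concentration `C` in Bq/mL,
   body weight `W` in g, injected dose `D` decay-corrected over the uptake
   time `t` with the F-18 half-life `T½ = 109.77 min`), plus the
   spleen-to-liver SUVmean ratio.
5. **Δ-uptake and cohort statistics** — post − pre changes per organ;
   Shapiro–Wilk-gated paired t / Wilcoxon signed-rank tests for pre-vs-post,
   gated Student t / Mann–Whitney U for group contrasts, Fisher/chi-square
   for categorical associations, and a cohort-median split of Δ-uptake
   against clinically observed irAE labels with an odds ratio.

Patient scans for this kind of retrospective study are not redistributable,
so the package ships a synthetic generator (`petirae.simulate`) producing
paired PET/CT phantom cohorts and tabular cohorts with the statistical
structure the analysis assumes: ellipsoidal organs with known baselines, hot
spherical lesions, additive noise, and label-conditional post-treatment
uptake shifts (thyroid ΔSUVmax ~ N(2.09, 1.54²) with a thyroid-related
event vs N(0.08, 1.12²) without; N(2.12, 0.71²) for hypothyroidism).

It is written for imaging scientists and biostatisticians who want a tested,
reproducible reference implementation of this screening analysis that plugs
into real segmentation outputs (NIfTI masks, one file per structure).

## Worked example

Simulate a 64-patient tabular cohort at the default study conditions and
analyze it:

```bash
petirae simulate tab --tabular --n-patients 64 --seed 1
petirae analyze tab tab
petirae report tab
```

prints (excerpt):

```
           thyroid suv_max        n=64  Δ=+0.392  paired_t               p=0.0068
           thyroid suv_mean       n=64  Δ=+0.131  paired_t               p=0.0985
          hip_bone suv_max        n=64  Δ=-0.026  paired_t               p=0.8670
    adrenal_glands suv_max        n=64  Δ=-0.011  paired_t               p=0.9342
median split        thyroid vs thyroid_related: OR=10.33 p=0.0265 (fisher_exact)
median split       hip_bone vs thyroid_related: OR=2.23 p=0.4741 (fisher_exact)
```

The thyroid shows a positive cohort-level ΔSUVmax with a significant paired
test, and patients above the median ΔSUVmax carry most of the
thyroid-related adverse events (odds ratio 10.3 at this seed); the null
organs (hip bone, adrenals, …) stay flat.  P-values are exploratory — with
15 paired rows per cohort an occasional null organ crosses 0.05 by chance
(an optional Benjamini–Hochberg column is available via `fdr_adjust`).

The image path runs the same analysis from NIfTI volumes:

```bash
petirae simulate study --n-patients 8 --seed 7   # paired PET/CT + masks + clinical.csv
petirae run study out --seed 7                   # masks → SUV → deltas → report
```

writing `measurements.csv`, `deltas.csv` and `stats_report.csv`/`.json`
(with the full run configuration embedded) into `out/`.  As a unit check,
a uniform 5000 Bq/mL volume acquired at 400 MBq / 80 kg / 60 min uptake
quantifies to SUV 1.4606 everywhere.

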