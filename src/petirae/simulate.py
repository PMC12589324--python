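"""Synthetic paired PET/CT phantom cohorts and tabular uptake cohorts.

No patient scans are redistributable for this kind of study, so testing and
demonstration run on two synthetic stand-ins that share one statistical
model:

* an **image phantom**: ellipsoidal organs with known baseline SUVmean,
  spherical hot tumor lesions, additive Gaussian noise, a co-registered CT
  with one distinct HU value per organ (the adapter path for external
  segmentations), and an independent post-treatment scan whose organ values
  are shifted by an injected per-organ Δ;
* a **tabular cohort**: per-patient adverse-event labels drawn at the
  clinical prevalences of an ICI PET screening cohort (n = 64; 11/64
  thyroid-related events of which 6 hypothyroidism, 4 hyperthyroidism,
  1 thyroiditis; 3/64 hepatitis; 4/64 colitis) and per-organ pre/Δ SUV
  values drawn from label-conditional normal distributions — for the
  thyroid, ΔSUVmax ~ N(2.09, 1.54²) under a thyroid-related event
  (N(2.12, 0.71²) for hypothyroidism) versus N(0.08, 1.12²) without one,
  and ΔSUVmean ~ N(0.91, 0.90²) / N(1.04, 0.59²) / N(0.07, 0.56²)
  respectively.  Non-thyroid organs are simulated as null (zero-mean Δ).

Geometry is analytic (ellipsoids/spheres), so erosion and quantification
admit construction oracles.  All randomness flows through one seeded
``numpy.random.Generator``; identical seeds give byte-identical cohorts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .masks import ORGAN_VOCABULARY, LesionSet, OrganSet
from .stats import AE_LABELS
from .volumes import (
    AcquisitionInfo,
    ImageVolume,
    LabelMask,
    suv_to_activity,
    write_mask,
    write_volume,
)

__all__ = [
    "OrganGeometry",
    "LesionSpec",
    "PhantomSpec",
    "PhantomPair",
    "OrganEffectModel",
    "CohortSimConfig",
    "default_phantom_spec",
    "make_phantom_pair",
    "simulate_tabular_cohort",
    "write_image_study",
    "CLINICAL_COLUMNS",
]


@dataclass(frozen=True)
class OrganGeometry:
    """An ellipsoidal organ: centre and semi-axes in mm, plus rendering values."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    baseline_suv_mean: float
    hu: float


@dataclass(frozen=True)
class LesionSpec:
    """A spherical hot tumor lesion."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    suv: float


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one synthetic patient.

    The CT grid is finer than the PET grid (as in clinical hybrid imaging);
    both share the physical frame.  Organs must not overlap and all geometry
    must lie inside the grid.
    """

    ct_shape: tuple[int, int, int] = (80, 80, 80)
    ct_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    pet_shape: tuple[int, int, int] = (40, 40, 40)
    pet_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    organs: dict[str, OrganGeometry] = field(default_factory=dict)
    lesions: list[LesionSpec] = field(default_factory=list)
    background_suv: float = 0.5
    background_hu: float = -100.0
    noise_sd: float = 0.1

    def validate(self) -> None:
        extent = [
            self.origin[i] + (self.ct_shape[i] - 1) * self.ct_spacing[i] for i in range(3)
        ]
        for name, g in self.organs.items():
            if name not in ORGAN_VOCABULARY:
                raise ValueError(f"unknown organ {name!r}")
            for i in range(3):
                lo = g.center_mm[i] - g.semi_axes_mm[i]
                hi = g.center_mm[i] + g.semi_axes_mm[i]
                if lo < self.origin[i] or hi > extent[i]:
                    raise ValueError(f"organ {name!r} extends outside the grid")
        for les in self.lesions:
            if les.suv <= self.background_suv:
                raise ValueError("lesion SUV must exceed the background")
            for i in range(3):
                if not (
                    self.origin[i]
                    <= les.center_mm[i] - les.radius_mm
                    and les.center_mm[i] + les.radius_mm <= extent[i]
                ):
                    raise ValueError("lesion extends outside the grid")
        # pairwise organ overlap, checked on the CT grid rendering
        names = list(self.organs)
        rendered = {n: self._inside(self.organs[n], self.ct_shape, self.ct_spacing) for n in names}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if np.any(rendered[a] & rendered[b]):
                    raise ValueError(f"organs {a!r} and {b!r} overlap")

    def _inside(self, g: OrganGeometry, shape, spacing) -> np.ndarray:
        axes = [
            (self.origin[i] + np.arange(shape[i]) * spacing[i] - g.center_mm[i])
            / g.semi_axes_mm[i]
            for i in range(3)
        ]
        return (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        ) <= 1.0

    def _sphere(self, les: LesionSpec, shape, spacing) -> np.ndarray:
        axes = [
            self.origin[i] + np.arange(shape[i]) * spacing[i] - les.center_mm[i]
            for i in range(3)
        ]
        return (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        ) <= les.radius_mm**2


#: Baseline organ SUVmean values and CT rendering values used by the default
#: phantom.  SUVmean magnitudes follow typical clinical cohort summaries
#: (thyroid 1.85, myocardium 2.37, pancreas 1.58, liver 2.33, hip bone 1.17,
#: adrenals 1.78); the spleen value 1.9 is a typical physiologic choice that
#: puts the spleen-to-liver ratio near 0.8.
DEFAULT_ORGANS: dict[str, OrganGeometry] = {
    "thyroid": OrganGeometry((40, 40, 130), (15, 10, 20), 1.85, 70.0),
    "myocardium": OrganGeometry((104, 48, 118), (25, 25, 22), 2.37, 45.0),
    "liver": OrganGeometry((52, 102, 82), (38, 30, 26), 2.33, 60.0),
    "spleen": OrganGeometry((120, 116, 84), (22, 18, 15), 1.90, 55.0),
    "pancreas": OrganGeometry((84, 52, 52), (30, 13, 12), 1.58, 40.0),
    "hip_bone": OrganGeometry((48, 48, 22), (30, 20, 14), 1.17, 700.0),
    "adrenal_glands": OrganGeometry((120, 112, 36), (12, 10, 14), 1.78, 35.0),
}

DEFAULT_LESIONS = [LesionSpec(center_mm=(52, 102, 82), radius_mm=6.0, suv=8.0)]


def default_phantom_spec(
    noise_sd: float = 0.1, with_lesion: bool = True
) -> PhantomSpec:
    """The standard 160 mm cube phantom: 2 mm CT grid, 4 mm PET grid, seven
    non-overlapping ellipsoidal organs, one 6 mm hot lesion in the liver."""
    spec = PhantomSpec(
        organs=dict(DEFAULT_ORGANS),
        lesions=list(DEFAULT_LESIONS) if with_lesion else [],
        noise_sd=noise_sd,
    )
    spec.validate()
    return spec


@dataclass
class PhantomPair:
    """One synthetic patient: paired PET (SUV), CT, and ground-truth masks."""

    pre_suv: ImageVolume
    post_suv: ImageVolume
    ct: ImageVolume
    organs: OrganSet  # ground truth, on the CT grid
    lesions: LesionSet  # on the PET grid
    acq_pre: AcquisitionInfo
    acq_post: AcquisitionInfo


def _draw_acquisition(rng: np.random.Generator) -> AcquisitionInfo:
    return AcquisitionInfo(
        injected_dose_mbq=float(np.clip(rng.normal(350.0, 30.0), 200.0, 500.0)),
        body_weight_kg=float(np.clip(rng.normal(78.0, 12.0), 45.0, 130.0)),
        uptake_time_min=float(np.clip(rng.normal(60.0, 5.0), 45.0, 90.0)),
    )


def make_phantom_pair(
    spec: PhantomSpec,
    injected_delta: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    baseline_scale: dict[str, float] | None = None,
) -> PhantomPair:
    """Render a paired pre/post phantom with an injected per-organ SUV shift.

    The pre image is organ baselines plus independent Gaussian noise; the
    post image additionally shifts each organ by ``injected_delta[organ]``
    (SUV units, default 0).  Lesions are rendered in both timepoints.
    ``baseline_scale`` optionally multiplies per-organ baselines to model
    inter-patient variability.  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    injected_delta = injected_delta or {}
    baseline_scale = baseline_scale or {}

    base = np.full(spec.pet_shape, spec.background_suv, dtype=np.float64)
    shift = np.zeros(spec.pet_shape, dtype=np.float64)
    ct = np.full(spec.ct_shape, spec.background_hu, dtype=np.float64)
    organ_masks: dict[str, LabelMask] = {}
    for name, g in spec.organs.items():
        pet_inside = spec._inside(g, spec.pet_shape, spec.pet_spacing)
        ct_inside = spec._inside(g, spec.ct_shape, spec.ct_spacing)
        value = g.baseline_suv_mean * baseline_scale.get(name, 1.0)
        base[pet_inside] = value
        shift[pet_inside] = injected_delta.get(name, 0.0)
        ct[ct_inside] = g.hu
        organ_masks[name] = LabelMask(
            data=ct_inside.astype(np.uint8),
            spacing=spec.ct_spacing,
            origin=spec.origin,
            label=name,
        )
    lesion_union = np.zeros(spec.pet_shape, dtype=bool)
    components = []
    for k, les in enumerate(spec.lesions):
        sph = spec._sphere(les, spec.pet_shape, spec.pet_spacing)
        lesion_union |= sph
        components.append(
            LabelMask(
                data=sph.astype(np.uint8),
                spacing=spec.pet_spacing,
                origin=spec.origin,
                label=f"lesion_{k}",
            )
        )
    pre = base.copy()
    post = base + shift
    for les in spec.lesions:
        sph = spec._sphere(les, spec.pet_shape, spec.pet_spacing)
        pre[sph] = les.suv
        post[sph] = les.suv
    if spec.noise_sd > 0:
        pre = np.clip(pre + rng.normal(0.0, spec.noise_sd, spec.pet_shape), 0.0, None)
        post = np.clip(post + rng.normal(0.0, spec.noise_sd, spec.pet_shape), 0.0, None)

    mk = lambda data: ImageVolume(
        data=data, spacing=spec.pet_spacing, origin=spec.origin, modality="PET", units="SUV"
    )
    lesion_set = LesionSet(
        union_mask=LabelMask(
            data=lesion_union.astype(np.uint8),
            spacing=spec.pet_spacing,
            origin=spec.origin,
            label="lesions",
        ),
        components=components or None,
    )
    return PhantomPair(
        pre_suv=mk(pre),
        post_suv=mk(post),
        ct=ImageVolume(
            data=ct, spacing=spec.ct_spacing, origin=spec.origin, modality="CT", units="HU"
        ),
        organs=OrganSet(organs=organ_masks),
        lesions=lesion_set,
        acq_pre=_draw_acquisition(rng),
        acq_post=_draw_acquisition(rng),
    )


# ---------------------------------------------------------------------------
# tabular cohort


@dataclass(frozen=True)
class OrganEffectModel:
    """Label-conditional pre/Δ distributions for one organ (normal models).

    ``pre_max``/``pre_mean`` are (mean, sd) of the pre-treatment SUV draws;
    the ``delta_*`` fields give (mean, sd) of the post − pre shift under no
    event, under the composite thyroid-related event, and under
    hypothyroidism specifically (the latter two fall back to the null model
    for organs that do not respond to the event).
    """

    pre_max: tuple[float, float]
    pre_mean: tuple[float, float]
    delta_max_null: tuple[float, float] = (0.0, 1.12)
    delta_mean_null: tuple[float, float] = (0.0, 0.56)
    delta_max_ae: tuple[float, float] | None = None
    delta_mean_ae: tuple[float, float] | None = None
    delta_max_hypo: tuple[float, float] | None = None
    delta_mean_hypo: tuple[float, float] | None = None


#: Default per-organ models.  Thyroid pre-treatment and effect parameters
#: follow the printed cohort summaries (pre SUVmax 3.06 ± 1.09, pre SUVmean
#: 1.85 ± 0.65; non-AE Δ 0.08 ± 1.12 / 0.07 ± 0.56; AE Δ 2.09 ± 1.54 /
#: 0.91 ± 0.90; hypothyroidism Δ 2.12 ± 0.71 / 1.04 ± 0.59).  Other organs
#: centre on the printed cohort medians with a 30% CV and zero-mean deltas.
DEFAULT_ORGAN_MODELS: dict[str, OrganEffectModel] = {
    "thyroid": OrganEffectModel(
        pre_max=(3.06, 1.09),
        pre_mean=(1.85, 0.65),
        delta_max_null=(0.08, 1.12),
        delta_mean_null=(0.07, 0.56),
        delta_max_ae=(2.09, 1.54),
        delta_mean_ae=(0.91, 0.90),
        delta_max_hypo=(2.12, 0.71),
        delta_mean_hypo=(1.04, 0.59),
    ),
    "myocardium": OrganEffectModel(pre_max=(7.72, 2.3), pre_mean=(2.37, 0.7)),
    "pancreas": OrganEffectModel(pre_max=(3.41, 1.0), pre_mean=(1.58, 0.47)),
    "liver": OrganEffectModel(pre_max=(5.17, 1.55), pre_mean=(2.33, 0.7)),
    "hip_bone": OrganEffectModel(pre_max=(3.86, 1.16), pre_mean=(1.17, 0.35)),
    "spleen": OrganEffectModel(pre_max=(2.60, 0.78), pre_mean=(1.90, 0.57)),
    "adrenal_glands": OrganEffectModel(pre_max=(2.50, 0.75), pre_mean=(1.78, 0.53)),
}

#: ICI drug frequencies of the emulated cohort with their checkpoint class.
DEFAULT_DRUGS = (
    ("pembrolizumab", "PD-1", 34),
    ("nivolumab", "PD-1", 16),
    ("atezolizumab", "PD-L1", 9),
    ("durvalumab", "PD-L1", 3),
    ("ipilimumab", "CTLA-4", 1),
    ("ipilimumab+nivolumab", "combination", 1),
)

CANCER_TYPES = (("lung", 36), ("melanoma", 20), ("lymphoma", 8))


@dataclass
class CohortSimConfig:
    """Study conditions of the emulated screening cohort."""

    n_patients: int = 64
    p_thyroid_related: float = 11 / 64
    #: subtype mix conditional on a thyroid-related event
    p_hypothyroidism_given_thyroid: float = 6 / 11
    p_hyperthyroidism_given_thyroid: float = 4 / 11
    p_hepatitis: float = 3 / 64
    p_colitis: float = 4 / 64
    organ_models: dict[str, OrganEffectModel] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_MODELS)
    )
    #: lab availability and pre/shift models (fT4 in ng/dL, fT3 in pg/mL)
    p_ft4_measured: float = 27 / 64
    p_ft3_measured: float = 21 / 64
    ft4_pre: tuple[float, float] = (1.2, 0.3)
    ft4_shift: tuple[float, float] = (-0.12, 0.59)
    ft3_pre: tuple[float, float] = (3.0, 0.5)
    ft3_shift: tuple[float, float] = (-0.81, 1.31)
    age: tuple[float, float] = (68.0, 14.4)
    p_male: float = 35 / 64
    scan_interval_mean_months: float = 4.5
    #: correlation between the SUVmax and SUVmean draws of one patient-organ
    #: (both pre values and deltas).  Marginals stay exactly at the
    #: configured normals; the correlation keeps max ≥ mean in most rows, as
    #: the two statistics move together in real scans.
    rho_max_mean: float = 0.8

    def validate(self) -> None:
        probs = [
            self.p_thyroid_related,
            self.p_hepatitis,
            self.p_colitis,
            self.p_ft4_measured,
            self.p_ft3_measured,
            self.p_male,
        ]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("prevalences must lie in [0, 1]")
        sub = self.p_hypothyroidism_given_thyroid + self.p_hyperthyroidism_given_thyroid
        if not (0.0 <= sub <= 1.0):
            raise ValueError(
                "thyroid subtype probabilities must sum to at most 1 "
                "(hypothyroidism cannot outnumber thyroid-related events)"
            )
        for name, m in self.organ_models.items():
            for pair in (m.pre_max, m.pre_mean, m.delta_max_null, m.delta_mean_null):
                if pair[1] <= 0:
                    raise ValueError(f"{name}: SDs must be positive")


CLINICAL_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "cancer_type",
    "ici_drug",
    "ici_class",
    "scan_interval_months",
    "none",
    *AE_LABELS,
    "ft3_pre",
    "ft3_post",
    "ft4_pre",
    "ft4_post",
]


def _draw_labels(rng: np.random.Generator, config: CohortSimConfig) -> dict[str, int]:
    labels = {l: 0 for l in AE_LABELS}
    if rng.random() < config.p_thyroid_related:
        labels["thyroid_related"] = 1
        u = rng.random()
        if u < config.p_hypothyroidism_given_thyroid:
            labels["hypothyroidism"] = 1
        elif u < config.p_hypothyroidism_given_thyroid + config.p_hyperthyroidism_given_thyroid:
            labels["hyperthyroidism"] = 1
        else:
            labels["thyroiditis"] = 1
    if rng.random() < config.p_hepatitis:
        labels["hepatitis"] = 1
    if rng.random() < config.p_colitis:
        labels["colitis"] = 1
    labels["none"] = int(not any(labels.values()))
    return labels


def _correlated_pair(
    rng: np.random.Generator,
    dist_a: tuple[float, float],
    dist_b: tuple[float, float],
    rho: float,
) -> tuple[float, float]:
    """One draw from a bivariate normal with the given marginals and rho."""
    z1, z2 = rng.standard_normal(2)
    a = dist_a[0] + dist_a[1] * z1
    b = dist_b[0] + dist_b[1] * (rho * z1 + math.sqrt(1.0 - rho**2) * z2)
    return float(a), float(b)


def draw_organ_delta(
    rng: np.random.Generator,
    model: OrganEffectModel,
    labels: dict[str, int],
    rho: float = 0.8,
) -> tuple[float, float]:
    """Draw (Δ SUVmax, Δ SUVmean) for one organ given the patient's labels."""
    if labels.get("hypothyroidism") and model.delta_max_hypo:
        mmax, mmean = model.delta_max_hypo, model.delta_mean_hypo
    elif labels.get("thyroid_related") and model.delta_max_ae:
        mmax, mmean = model.delta_max_ae, model.delta_mean_ae
    else:
        mmax, mmean = model.delta_max_null, model.delta_mean_null
    return _correlated_pair(rng, mmax, mmean, rho)


def simulate_tabular_cohort(
    config: CohortSimConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort: clinical records, measurements, and deltas.

    Returns ``(records, measurements, deltas)`` as tidy DataFrames in the
    same schemas the image pipeline produces, so the statistical stage is
    agnostic to which path generated its input.  SUVmax and SUVmean draws
    are correlated (``config.rho_max_mean``) with the configured marginals
    preserved exactly; pre and post values are truncated at 0.05 SUV.  The
    correlation keeps max ≥ mean in most rows but does not enforce it — the
    cohort analyses treat the two statistics as parallel markers and never
    compare them within a row.
    """
    config = config or CohortSimConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    records, meas_rows, delta_rows = [], [], []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        labels = _draw_labels(rng, config)
        drug_names, classes, weights = zip(*DEFAULT_DRUGS)
        drug_idx = rng.choice(len(drug_names), p=np.array(weights) / sum(weights))
        cancer = rng.choice(
            [c for c, _ in CANCER_TYPES],
            p=np.array([w for _, w in CANCER_TYPES]) / sum(w for _, w in CANCER_TYPES),
        )
        rec = {
            "patient_id": pid,
            "age": float(np.clip(rng.normal(*config.age), 18, 95)),
            "sex": "male" if rng.random() < config.p_male else "female",
            "cancer_type": str(cancer),
            "ici_drug": drug_names[drug_idx],
            "ici_class": classes[drug_idx],
            "scan_interval_months": float(
                max(0.5, rng.exponential(config.scan_interval_mean_months))
            ),
            **labels,
        }
        for marker, p_measured, pre_model, shift_model in (
            ("ft4", config.p_ft4_measured, config.ft4_pre, config.ft4_shift),
            ("ft3", config.p_ft3_measured, config.ft3_pre, config.ft3_shift),
        ):
            if rng.random() < p_measured:
                pre_v = float(rng.normal(*pre_model))
                rec[f"{marker}_pre"] = pre_v
                rec[f"{marker}_post"] = pre_v + float(rng.normal(*shift_model))
            else:
                rec[f"{marker}_pre"] = math.nan
                rec[f"{marker}_post"] = math.nan
        records.append(rec)

        for organ, model in config.organ_models.items():
            pre_max, pre_mean = _correlated_pair(
                rng, model.pre_max, model.pre_mean, config.rho_max_mean
            )
            pre_max, pre_mean = max(0.05, pre_max), max(0.05, pre_mean)
            d_max, d_mean = draw_organ_delta(rng, model, labels, rho=config.rho_max_mean)
            post_max = max(0.05, pre_max + d_max)
            post_mean = max(0.05, pre_mean + d_mean)
            for tp, smax, smean in (("pre", pre_max, pre_mean), ("post", post_max, post_mean)):
                meas_rows.append(
                    {
                        "patient_id": pid,
                        "organ": organ,
                        "timepoint": tp,
                        "suv_max": smax,
                        "suv_mean": smean,
                        "voxel_count": 1000,
                        "empty_flag": False,
                    }
                )
            delta_rows.append(
                {
                    "patient_id": pid,
                    "organ": organ,
                    "delta_suv_max": post_max - pre_max,
                    "delta_suv_mean": post_mean - pre_mean,
                }
            )
    records_df = pd.DataFrame(records, columns=CLINICAL_COLUMNS)
    measurements_df = pd.DataFrame(meas_rows).sort_values(
        ["patient_id", "organ", "timepoint"], ignore_index=True
    )
    deltas_df = pd.DataFrame(delta_rows).sort_values(
        ["patient_id", "organ"], ignore_index=True
    )
    return records_df, measurements_df, deltas_df


# ---------------------------------------------------------------------------
# full synthetic study directory (image path)


def write_image_study(
    out_dir: str | Path,
    n_patients: int = 4,
    seed: int = 0,
    config: CohortSimConfig | None = None,
    spec: PhantomSpec | None = None,
) -> Path:
    """Write a complete synthetic study directory the pipeline can consume.

    Layout (one file per structure)::

        <out>/clinical.csv
        <out>/<pid>_<tp>_pet.nii.gz        activity concentration (Bq/mL)
        <out>/<pid>_<tp>_pet.json          acquisition sidecar
        <out>/<pid>_<tp>_ct.nii.gz
        <out>/<pid>_<tp>_<organ>.nii.gz    organ masks on the CT grid
        <out>/<pid>_<tp>_lesions.nii.gz    lesion union on the PET grid

    Per-patient thyroid (and other-organ) Δs are drawn from the same
    label-conditional model as the tabular path, injected as SUVmean shifts
    into the post image; per-patient baselines are jittered so patients are
    not clones.
    """
    config = config or CohortSimConfig()
    config.validate()
    spec = spec or default_phantom_spec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(seed)
    records = []
    for i in range(n_patients):
        pid = f"P{i:04d}"
        rng = np.random.default_rng(root_rng.integers(0, 2**31 - 1))
        labels = _draw_labels(rng, config)
        injected: dict[str, float] = {}
        scale: dict[str, float] = {}
        for organ, model in config.organ_models.items():
            if organ not in spec.organs:
                continue
            _, d_mean = draw_organ_delta(rng, model, labels)
            injected[organ] = d_mean
            scale[organ] = float(np.clip(rng.normal(1.0, 0.15), 0.5, 1.6))
        pair = make_phantom_pair(spec, injected_delta=injected, seed=rng, baseline_scale=scale)
        for tp, suv, acq in (("pre", pair.pre_suv, pair.acq_pre), ("post", pair.post_suv, pair.acq_post)):
            write_volume(suv_to_activity(suv, acq), out / f"{pid}_{tp}_pet.nii.gz")
            acq.to_json(out / f"{pid}_{tp}_pet.json")
            write_volume(pair.ct, out / f"{pid}_{tp}_ct.nii.gz")
            for organ, mask in pair.organs:
                write_mask(mask, out / f"{pid}_{tp}_{organ}.nii.gz")
            write_mask(pair.lesions.union_mask, out / f"{pid}_{tp}_lesions.nii.gz")
        rec = {
            "patient_id": pid,
            "age": float(np.clip(rng.normal(*config.age), 18, 95)),
            "sex": "male" if rng.random() < config.p_male else "female",
            "cancer_type": "lung",
            "ici_drug": "pembrolizumab",
            "ici_class": "PD-1",
            "scan_interval_months": float(max(0.5, rng.exponential(config.scan_interval_mean_months))),
            **labels,
            "ft3_pre": math.nan,
            "ft3_post": math.nan,
            "ft4_pre": math.nan,
            "ft4_post": math.nan,
        }
        records.append(rec)
    pd.DataFrame(records, columns=CLINICAL_COLUMNS).to_csv(
        out / "clinical.csv", index=False, float_format="%.9g",
        quoting=csv.QUOTE_MINIMAL, lineterminator="\n",
    )
    return out
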