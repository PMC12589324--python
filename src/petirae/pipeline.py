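"""End-to-end orchestration: study directory → measurements → report.

The pipeline consumes a study directory in the documented layout (PET
activity volumes with acquisition sidecars, CT volumes, one binary NIfTI
mask per organ on the CT grid, a lesion-union mask on the PET grid, and a
clinical CSV) and runs: mask preparation (transfer → erosion → lesion
removal) → per-organ SUV quantification → pre/post deltas → the cohort
statistics report.  Segmentation masks are *inputs* (adapter pattern): the
deep-learning segmentation tools that produce them in a clinical deployment
run upstream of this package.

Stages persist intermediate CSVs, so ``analyze`` can be re-run from cached
measurements, and identical config + seed reproduces byte-identical report
files (images are not byte-compared: gzip embeds timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import quantify as q
from .masks import (
    ORGAN_VOCABULARY,
    LesionSet,
    OrganSet,
    prepare_organ_masks,
    read_label_manifest,
)
from .stats import ReportConfig, build_cohort_report
from .volumes import AcquisitionInfo, read_mask, read_volume, to_suv, write_mask

__all__ = ["RunConfig", "run_pipeline", "stage_quantify", "stage_analyze", "stage_prepare_masks"]

log = logging.getLogger("petirae")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; serialized into the report."""

    input_dir: str
    output_dir: str
    margin_mm: float = 4.0
    lesion_margin_mm: float = 0.0
    erode_before_resample: bool = False
    alpha_shapiro: float = 0.05
    split_statistic: str = "delta_suv_max"
    split: str = "median"
    or_estimator: str = "sample"
    fdr_adjust: bool = False
    group_variable: str = "hypothyroidism"
    organs: tuple[str, ...] = ORGAN_VOCABULARY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin_mm < 0:
            raise ValueError("margin_mm must be nonnegative")
        unknown = set(self.organs) - set(ORGAN_VOCABULARY)
        if unknown:
            raise ValueError(f"unknown organs in config: {sorted(unknown)}")
        self.organs = tuple(self.organs)

    def report_config(self) -> ReportConfig:
        return ReportConfig(
            alpha_shapiro=self.alpha_shapiro,
            split_statistic=self.split_statistic,
            split=self.split,
            or_estimator=self.or_estimator,
            fdr_adjust=self.fdr_adjust,
            group_variable=self.group_variable,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "organs" in data:
            data["organs"] = tuple(data["organs"])
        return cls(**data)


def _discover_patients(study_dir: Path) -> list[str]:
    clinical = study_dir / "clinical.csv"
    if clinical.exists():
        return sorted(pd.read_csv(clinical)["patient_id"].astype(str))
    pids = {p.name.split("_")[0] for p in study_dir.glob("*_pre_pet.nii*")}
    return sorted(pids)


def _load_patient_masks(study_dir: Path, pid: str, tp: str, organs) -> tuple[OrganSet, LesionSet | None]:
    # optional adapter manifest: external tool label names -> organ vocabulary
    aliases: dict[str, list[str]] = {}
    manifest = study_dir / "labels.json"
    if manifest.exists():
        for external, internal in read_label_manifest(manifest).items():
            aliases.setdefault(internal, []).append(external)
    organ_masks = {}
    for organ in organs:
        candidates = [organ] + aliases.get(organ, [])
        found = None
        for name in candidates:
            for suffix in (".nii.gz", ".nii"):
                path = study_dir / f"{pid}_{tp}_{name}{suffix}"
                if path.exists():
                    found = path
                    break
            if found:
                break
        if found is not None:
            organ_masks[organ] = read_mask(found, label=organ)
        else:
            log.warning("%s/%s: no mask file for organ %r", pid, tp, organ)
    lesions = None
    for suffix in (".nii.gz", ".nii"):
        path = study_dir / f"{pid}_{tp}_lesions{suffix}"
        if path.exists():
            lesions = LesionSet(union_mask=read_mask(path, label="lesions"))
            break
    return OrganSet(organs=organ_masks), lesions


def _load_suv(study_dir: Path, pid: str, tp: str):
    for suffix in (".nii.gz", ".nii"):
        pet_path = study_dir / f"{pid}_{tp}_pet{suffix}"
        if pet_path.exists():
            break
    else:
        raise FileNotFoundError(f"{pid}/{tp}: no PET volume in {study_dir}")
    sidecar = study_dir / f"{pid}_{tp}_pet.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"{pid}/{tp}: missing acquisition sidecar {sidecar.name}")
    pet = read_volume(pet_path, modality="PET", units="Bq_per_mL")
    acq = AcquisitionInfo.from_json(sidecar)
    return to_suv(pet, acq)


def stage_prepare_masks(config: RunConfig) -> Path:
    """Write the prepared (PET-grid, eroded, lesion-free) masks to disk.

    Optional inspection stage; ``stage_quantify`` prepares masks on the fly
    and does not require it.
    """
    study = Path(config.input_dir)
    out = Path(config.output_dir) / "prepared_masks"
    out.mkdir(parents=True, exist_ok=True)
    for pid in _discover_patients(study):
        for tp in ("pre", "post"):
            try:
                suv = _load_suv(study, pid, tp)
            except FileNotFoundError as err:
                log.warning("%s", err)
                continue
            organs, lesions = _load_patient_masks(study, pid, tp, config.organs)
            prepared = prepare_organ_masks(
                organs,
                lesions,
                suv,
                margin_mm=config.margin_mm,
                lesion_margin_mm=config.lesion_margin_mm,
                erode_before_resample=config.erode_before_resample,
            )
            for organ, mask in prepared:
                write_mask(mask, out / f"{pid}_{tp}_{organ}_prepared.nii.gz")
    return out


def stage_quantify(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Prepare masks and quantify every patient × organ × timepoint.

    Persists ``measurements.csv`` and ``deltas.csv`` in the output directory.
    Missing files skip the affected patient-timepoint with a warning; empty
    prepared masks yield flagged rows.
    """
    study = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    measurements = []
    for pid in _discover_patients(study):
        for tp in ("pre", "post"):
            try:
                suv = _load_suv(study, pid, tp)
            except FileNotFoundError as err:
                log.warning("skipping: %s", err)
                continue
            organs, lesions = _load_patient_masks(study, pid, tp, config.organs)
            prepared = prepare_organ_masks(
                organs,
                lesions,
                suv,
                margin_mm=config.margin_mm,
                lesion_margin_mm=config.lesion_margin_mm,
                erode_before_resample=config.erode_before_resample,
            )
            empties = prepared.empty_organs()
            if empties:
                log.warning("%s/%s: empty prepared masks for %s", pid, tp, empties)
            for organ, mask in prepared:
                measurements.append(q.quantify_organ(suv, mask, pid, organ, tp))
    meas_df = q.measurements_to_frame(measurements)
    deltas_df = q.deltas_from_measurements(meas_df)
    _write_csv(meas_df, out / "measurements.csv")
    _write_csv(deltas_df, out / "deltas.csv")
    log.info("quantified %d measurements, %d deltas", len(meas_df), len(deltas_df))
    return meas_df, deltas_df


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g", lineterminator="\n")


def stage_analyze(
    config: RunConfig,
    measurements: pd.DataFrame | None = None,
    deltas: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the cohort statistics and write ``stats_report.csv`` / ``.json``.

    Reads cached ``measurements.csv``/``deltas.csv`` from the output
    directory when not handed frames directly, so the stage is re-runnable
    and idempotent on cached intermediates.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    clinical_path = Path(config.input_dir) / "clinical.csv"
    if clinical_path.exists():
        records = pd.read_csv(clinical_path)
        records["patient_id"] = records["patient_id"].astype(str)
    else:
        log.warning("no clinical.csv in %s; AE associations unavailable", config.input_dir)
        records = pd.DataFrame(columns=["patient_id"])
    if measurements is None:
        measurements = pd.read_csv(out / "measurements.csv")
        measurements["patient_id"] = measurements["patient_id"].astype(str)
    if deltas is None:
        deltas = pd.read_csv(out / "deltas.csv")
        deltas["patient_id"] = deltas["patient_id"].astype(str)
    report = build_cohort_report(records, measurements, deltas, config.report_config())

    stacked = []
    for section, df in report.items():
        if df.empty:
            continue
        d = df.copy()
        d.insert(0, "section", section)
        stacked.append(d)
    flat = pd.concat(stacked, ignore_index=True, sort=False) if stacked else pd.DataFrame()
    _write_csv(flat, out / "stats_report.csv")

    payload = {
        "config": asdict(config) | {"organs": list(config.organs)},
        "sections": {
            name: json.loads(df.to_json(orient="records", double_precision=9))
            for name, df in report.items()
        },
    }
    (out / "stats_report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n"
    )
    log.info("report written to %s", out)
    return report


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute all stages in order and return the report tables."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("pipeline start: %s", asdict(config))
        meas, deltas = stage_quantify(config)
        report = stage_analyze(config, meas, deltas)
        log.info("pipeline done")
    finally:
        log.removeHandler(handler)
        handler.close()
    return report
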