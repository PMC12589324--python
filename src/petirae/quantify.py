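"""Per-organ SUV statistics, the spleen-to-liver ratio, and pre/post deltas.

SUVmax is the maximum and SUVmean the plain arithmetic mean of the SUV field
over the prepared organ mask (after erosion and lesion removal).  The delta
convention is post − pre: a positive Δ is an uptake increase after therapy.
Organs whose prepared mask is empty yield a flagged measurement with NaN
statistics; a patient missing either timepoint for an organ is excluded from
that organ's paired analysis only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import ImageVolume, LabelMask, grids_equal

__all__ = [
    "UptakeMeasurement",
    "DeltaUptake",
    "MissingOrganError",
    "quantify_organ",
    "spleen_liver_ratio",
    "compute_delta",
    "measurements_to_frame",
    "deltas_to_frame",
    "deltas_from_measurements",
]


class MissingOrganError(ValueError):
    """A required organ measurement is absent or empty."""


@dataclass(frozen=True)
class UptakeMeasurement:
    """SUV statistics of one organ for one patient at one timepoint."""

    patient_id: str
    organ: str
    timepoint: str  # "pre" | "post"
    suv_max: float
    suv_mean: float
    voxel_count: int
    empty_flag: bool = False

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre", "post"):
            raise ValueError(f"timepoint must be 'pre' or 'post', got {self.timepoint!r}")
        if self.empty_flag != (self.voxel_count == 0):
            raise ValueError("empty_flag must mirror voxel_count == 0")
        if self.voxel_count >= 1 and not (
            self.suv_mean <= self.suv_max + 1e-9
        ):
            raise ValueError("suv_mean cannot exceed suv_max")


@dataclass(frozen=True)
class DeltaUptake:
    """Post − pre uptake change of one organ for one patient."""

    patient_id: str
    organ: str
    delta_suv_max: float
    delta_suv_mean: float


def quantify_organ(
    suv: ImageVolume,
    mask: LabelMask,
    patient_id: str,
    organ: str,
    timepoint: str,
) -> UptakeMeasurement:
    """Compute SUVmax/SUVmean of ``suv`` over ``mask``.

    An empty mask produces a flagged measurement with NaN statistics instead
    of raising, so a cohort run survives organs erased by erosion.
    """
    if suv.units != "SUV":
        raise ValueError("quantify_organ expects a volume in SUV units")
    if not grids_equal(suv, mask):
        raise ValueError(f"mask for {organ!r} is not on the SUV volume's grid")
    values = np.asarray(suv.data)[mask.data.astype(bool)]
    if values.size == 0:
        return UptakeMeasurement(
            patient_id=patient_id,
            organ=organ,
            timepoint=timepoint,
            suv_max=math.nan,
            suv_mean=math.nan,
            voxel_count=0,
            empty_flag=True,
        )
    return UptakeMeasurement(
        patient_id=patient_id,
        organ=organ,
        timepoint=timepoint,
        suv_max=float(values.max()),
        suv_mean=float(values.mean()),
        voxel_count=int(values.size),
    )


def spleen_liver_ratio(measurements) -> float:
    """Spleen SUVmean divided by liver SUVmean for one patient-timepoint.

    A systemic immune-activation marker; requires non-empty spleen and liver
    measurements and strictly positive liver uptake.
    """
    by_organ = {m.organ: m for m in measurements}
    for organ in ("spleen", "liver"):
        m = by_organ.get(organ)
        if m is None or m.empty_flag:
            raise MissingOrganError(f"no usable {organ} measurement")
    liver = by_organ["liver"].suv_mean
    if liver <= 0:
        raise MissingOrganError("liver SUVmean must be positive for the ratio")
    return by_organ["spleen"].suv_mean / liver


def compute_delta(pre: UptakeMeasurement, post: UptakeMeasurement) -> DeltaUptake:
    """Post − pre change of SUVmax and SUVmean for one patient-organ."""
    if pre.patient_id != post.patient_id or pre.organ != post.organ:
        raise ValueError("pre and post must refer to the same patient and organ")
    if pre.timepoint != "pre" or post.timepoint != "post":
        raise ValueError("arguments must be (pre, post) in that order")
    if pre.empty_flag or post.empty_flag:
        raise MissingOrganError(
            f"{pre.patient_id}/{pre.organ}: delta undefined with an empty timepoint"
        )
    return DeltaUptake(
        patient_id=pre.patient_id,
        organ=pre.organ,
        delta_suv_max=post.suv_max - pre.suv_max,
        delta_suv_mean=post.suv_mean - pre.suv_mean,
    )


# -- tidy-frame adapters (one row per patient × organ × timepoint) -----------

MEASUREMENT_COLUMNS = [
    "patient_id",
    "organ",
    "timepoint",
    "suv_max",
    "suv_mean",
    "voxel_count",
    "empty_flag",
]

DELTA_COLUMNS = ["patient_id", "organ", "delta_suv_max", "delta_suv_mean"]


def measurements_to_frame(measurements) -> pd.DataFrame:
    rows = [
        {
            "patient_id": m.patient_id,
            "organ": m.organ,
            "timepoint": m.timepoint,
            "suv_max": m.suv_max,
            "suv_mean": m.suv_mean,
            "voxel_count": m.voxel_count,
            "empty_flag": m.empty_flag,
        }
        for m in measurements
    ]
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return df.sort_values(["patient_id", "organ", "timepoint"], ignore_index=True)


def deltas_to_frame(deltas) -> pd.DataFrame:
    rows = [
        {
            "patient_id": d.patient_id,
            "organ": d.organ,
            "delta_suv_max": d.delta_suv_max,
            "delta_suv_mean": d.delta_suv_mean,
        }
        for d in deltas
    ]
    df = pd.DataFrame(rows, columns=DELTA_COLUMNS)
    return df.sort_values(["patient_id", "organ"], ignore_index=True)


def deltas_from_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    """Pair pre/post rows patient-organ-wise and compute post − pre deltas.

    Patients missing either timepoint (or with an empty mask at either) for
    an organ are dropped from that organ only.
    """
    usable = measurements[~measurements["empty_flag"].astype(bool)]
    wide = usable.pivot_table(
        index=["patient_id", "organ"],
        columns="timepoint",
        values=["suv_max", "suv_mean"],
        aggfunc="first",
    )
    rows = []
    for (pid, organ), row in wide.iterrows():
        try:
            pre_max, post_max = row[("suv_max", "pre")], row[("suv_max", "post")]
            pre_mean, post_mean = row[("suv_mean", "pre")], row[("suv_mean", "post")]
        except KeyError:
            continue
        if any(pd.isna(v) for v in (pre_max, post_max, pre_mean, post_mean)):
            continue
        rows.append(
            {
                "patient_id": pid,
                "organ": organ,
                "delta_suv_max": post_max - pre_max,
                "delta_suv_mean": post_mean - pre_mean,
            }
        )
    df = pd.DataFrame(rows, columns=DELTA_COLUMNS)
    return df.sort_values(["patient_id", "organ"], ignore_index=True)
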