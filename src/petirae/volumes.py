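"""Volumetric image containers, NIfTI-1 round-trip IO, and SUV conversion.

The in-memory model is deliberately minimal: an axis-aligned 3D scalar grid
with millimetre spacing and origin (the physical coordinate of the centre of
voxel ``(0, 0, 0)``).  All physical reasoning downstream (mask transfer,
metric erosion) goes through ``spacing``/``origin``; the voxel array is kept
in the axis order delivered by the reader so that no silent permutation can
occur between CT and PET grids.

PET activity concentration (Bq/mL) is converted to the body-weight
standardized uptake value

    SUV = C / (D_decayed / W),   D_decayed = D * 2**(-t / T_half)

with ``C`` the activity concentration, ``W`` the body weight in grams
(tissue density 1 g/mL assumed, the standard clinical convention), ``D`` the
injected dose in Bq decay-corrected over the uptake time ``t`` using the
F-18 half-life ``T_half`` (109.77 min by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "AcquisitionInfo",
    "LabelMask",
    "VolumeFormatError",
    "F18_HALF_LIFE_MIN",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "to_suv",
    "suv_to_activity",
    "grids_equal",
]

F18_HALF_LIFE_MIN = 109.77

MODALITY_UNITS = {"CT": {"HU"}, "PET": {"Bq_per_mL", "SUV"}}


class VolumeFormatError(ValueError):
    """Raised for malformed on-disk volumes (wrong rank, bad header fields)."""


def _check_grid(data: np.ndarray, spacing, origin) -> None:
    if data.ndim != 3 or min(data.shape) < 1:
        raise VolumeFormatError(
            f"expected a 3D volume, got shape {data.shape}"
        )
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if spacing.shape != (3,) or origin.shape != (3,):
        raise VolumeFormatError("spacing and origin must each have 3 entries")
    if not np.all(spacing > 0):
        raise VolumeFormatError(f"spacing must be strictly positive, got {tuple(spacing)}")


@dataclass
class ImageVolume:
    """A 3D scalar field on an axis-aligned physical grid.

    Parameters
    ----------
    data
        3D array; axis order is (x, y, z) as stored on disk.
    spacing
        Voxel size in mm per axis, strictly positive.
    origin
        Physical coordinate (mm) of the centre of voxel (0, 0, 0).
    modality
        ``"CT"`` or ``"PET"``.
    units
        ``"HU"`` for CT; ``"Bq_per_mL"`` or ``"SUV"`` for PET.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "PET"
    units: str = "Bq_per_mL"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_grid(self.data, self.spacing, self.origin)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.modality not in MODALITY_UNITS:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.units not in MODALITY_UNITS[self.modality]:
            raise ValueError(
                f"units {self.units!r} inconsistent with modality {self.modality!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def with_data(self, data: np.ndarray, units: str | None = None) -> "ImageVolume":
        return replace(self, data=data, units=units or self.units)


@dataclass
class LabelMask:
    """A binary mask bound to the same grid model as :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_grid(self.data, self.spacing, self.origin)
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {vals[:5]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_count(self) -> int:
        return int(self.data.sum())

    def voxel_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def with_data(self, data: np.ndarray) -> "LabelMask":
        return replace(self, data=data)


@dataclass
class AcquisitionInfo:
    """Injection and timing metadata needed for body-weight SUV.

    All quantities strictly positive; ``uptake_time_min`` is bounded by ten
    half-lives as a sanity check against unit mix-ups (a realistic FDG uptake
    time is ~60 min).
    """

    injected_dose_mbq: float
    body_weight_kg: float
    uptake_time_min: float
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        for name in ("injected_dose_mbq", "body_weight_kg", "half_life_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.uptake_time_min < 0:
            raise ValueError("uptake_time_min must be nonnegative")
        if self.uptake_time_min >= 10 * self.half_life_min:
            raise ValueError("uptake_time_min exceeds 10 half-lives; check units")

    @property
    def decayed_dose_bq(self) -> float:
        """Injected dose in Bq, decay-corrected to scan time."""
        return self.injected_dose_mbq * 1e6 * 2.0 ** (-self.uptake_time_min / self.half_life_min)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "injected_dose_mbq": self.injected_dose_mbq,
                    "body_weight_kg": self.body_weight_kg,
                    "uptake_time_min": self.uptake_time_min,
                    "half_life_min": self.half_life_min,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionInfo":
        d = json.loads(Path(path).read_text())
        return cls(
            injected_dose_mbq=float(d["injected_dose_mbq"]),
            body_weight_kg=float(d["body_weight_kg"]),
            uptake_time_min=float(d["uptake_time_min"]),
            half_life_min=float(d.get("half_life_min", F18_HALF_LIFE_MIN)),
        )


def _load_nifti(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) != 3:
        raise VolumeFormatError(
            f"{path.name}: header field 'dim' describes a {len(shape)}D image; expected 3D"
        )
    zooms = img.header.get_zooms()[:3]
    if not all(z > 0 for z in zooms):
        raise VolumeFormatError(
            f"{path.name}: header field 'pixdim' has non-positive spacing {zooms}"
        )
    affine = img.affine
    # Axis-aligned grid model: spacing is the column norm, origin the
    # translation of the qform/sform in the file's native (RAS) frame.
    spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
    origin = tuple(float(v) for v in affine[:3, 3])
    data = np.asanyarray(img.dataobj)
    return data, spacing, origin


def read_volume(
    path: str | Path, modality: str = "PET", units: str | None = None
) -> ImageVolume:
    """Read a NIfTI-1 volume (optionally .gz) into an :class:`ImageVolume`.

    NIfTI carries no modality/units; the caller states them (defaults:
    PET in Bq/mL, CT in HU).
    """
    data, spacing, origin = _load_nifti(path)
    if units is None:
        units = "HU" if modality == "CT" else "Bq_per_mL"
    return ImageVolume(
        data=np.asarray(data, dtype=np.float32),
        spacing=spacing,
        origin=origin,
        modality=modality,
        units=units,
    )


def read_mask(path: str | Path, label: str = "") -> LabelMask:
    """Read a binary NIfTI mask; any nonzero voxel is treated as foreground."""
    data, spacing, origin = _load_nifti(path)
    return LabelMask(
        data=(np.asarray(data) > 0.5).astype(np.uint8),
        spacing=spacing,
        origin=origin,
        label=label or Path(path).name.split(".")[0],
    )


def _write_nifti(data: np.ndarray, spacing, origin, path: str | Path) -> None:
    affine = np.diag(list(spacing) + [1.0]).astype(float)
    affine[:3, 3] = origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write to NIfTI-1; scalar data is stored as float32."""
    _write_nifti(np.asarray(vol.data, dtype=np.float32), vol.spacing, vol.origin, path)


def write_mask(mask: LabelMask, path: str | Path) -> None:
    _write_nifti(mask.data.astype(np.uint8), mask.spacing, mask.origin, path)


def to_suv(pet: ImageVolume, acq: AcquisitionInfo) -> ImageVolume:
    """Convert a PET activity-concentration volume (Bq/mL) to body-weight SUV.

    SUV = C * W_grams / D_decayed, with the injected dose decay-corrected to
    scan time.  Linear in the activity; a uniform concentration equal to
    D_decayed/W maps to SUV 1.0 exactly.
    """
    if pet.modality != "PET" or pet.units != "Bq_per_mL":
        raise ValueError("to_suv expects a PET volume in Bq_per_mL")
    w_grams = acq.body_weight_kg * 1000.0
    factor = w_grams / acq.decayed_dose_bq
    return ImageVolume(
        data=np.asarray(pet.data, dtype=np.float64) * factor,
        spacing=pet.spacing,
        origin=pet.origin,
        modality="PET",
        units="SUV",
    )


def suv_to_activity(suv: ImageVolume, acq: AcquisitionInfo) -> ImageVolume:
    """Inverse of :func:`to_suv`; used when writing synthetic PET studies."""
    if suv.units != "SUV":
        raise ValueError("expected a volume in SUV units")
    factor = acq.decayed_dose_bq / (acq.body_weight_kg * 1000.0)
    return ImageVolume(
        data=np.asarray(suv.data, dtype=np.float64) * factor,
        spacing=suv.spacing,
        origin=suv.origin,
        modality="PET",
        units="Bq_per_mL",
    )


def grids_equal(a, b, tol: float = 1e-6) -> bool:
    """True when two volumes/masks share shape, spacing and origin."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=tol)
        and np.allclose(a.origin, b.origin, atol=tol)
    )
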