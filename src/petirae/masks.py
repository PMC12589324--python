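"""Mask operations: CT→PET grid transfer, metric erosion, lesion exclusion.

These are the geometric preprocessing steps applied to automatically
segmented organ masks before any uptake is quantified: masks delineated on
the CT grid are transferred to the co-registered (coarser) PET grid by
nearest-neighbor assignment of physical voxel centres, shrunk by a physical
safety margin (default 4 mm) to absorb segmentation and co-registration
inaccuracies, and cleared of tumor-lesion voxels so that malignant uptake
does not contaminate organ-level statistics.

Erosion is defined metrically, not in voxels: a voxel survives iff its
Euclidean distance — computed in millimetres with the grid's anisotropic
spacing — to the nearest background voxel is strictly greater than the
radius.  A voxel-count structuring element would shrink anisotropic grids
by different physical amounts per axis and is deliberately not offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, LabelMask, grids_equal

__all__ = [
    "ORGAN_VOCABULARY",
    "OrganSet",
    "LesionSet",
    "GridMismatchError",
    "resample_mask_to_grid",
    "erode_mm",
    "remove_lesions",
    "prepare_organ_masks",
]

#: The seven organs quantified for adverse-event screening.
ORGAN_VOCABULARY = (
    "thyroid",
    "myocardium",
    "pancreas",
    "liver",
    "hip_bone",
    "spleen",
    "adrenal_glands",
)


class GridMismatchError(ValueError):
    """Raised when an operation requires two objects on the same grid."""


def read_label_manifest(path) -> dict[str, str]:
    """Read an adapter manifest mapping external segmentation-tool label
    names to the internal organ vocabulary.

    The JSON object maps ``{"<external name>": "<internal organ>"}``, e.g.
    ``{"thyroid_gland": "thyroid", "heart_myocardium": "myocardium"}``.
    Every target must be in :data:`ORGAN_VOCABULARY`.
    """
    import json
    from pathlib import Path

    mapping = json.loads(Path(path).read_text())
    bad = {v for v in mapping.values() if v not in ORGAN_VOCABULARY}
    if bad:
        raise ValueError(f"manifest targets outside the organ vocabulary: {sorted(bad)}")
    return {str(k): str(v) for k, v in mapping.items()}


@dataclass
class OrganSet:
    """A named collection of organ masks sharing one grid."""

    organs: dict[str, LabelMask]

    def __post_init__(self) -> None:
        for name in self.organs:
            if name not in ORGAN_VOCABULARY:
                raise ValueError(
                    f"unknown organ {name!r}; vocabulary: {ORGAN_VOCABULARY}"
                )
        masks = list(self.organs.values())
        for m in masks[1:]:
            if not grids_equal(m, masks[0]):
                raise GridMismatchError("all organ masks must share one grid")

    def __iter__(self):
        return iter(self.organs.items())

    def __getitem__(self, name: str) -> LabelMask:
        return self.organs[name]

    def empty_organs(self) -> list[str]:
        """Organs whose mask has no voxels (e.g. erased by erosion)."""
        return sorted(n for n, m in self.organs.items() if m.voxel_count() == 0)


@dataclass
class LesionSet:
    """The union of all tumor-lesion masks, optionally with components."""

    union_mask: LabelMask
    components: list[LabelMask] | None = None

    def __post_init__(self) -> None:
        if self.components:
            acc = np.zeros_like(self.union_mask.data)
            for c in self.components:
                if not grids_equal(c, self.union_mask):
                    raise GridMismatchError("lesion components must share the union grid")
                acc |= c.data
            if not np.array_equal(acc, self.union_mask.data):
                raise ValueError("union_mask must equal the OR of components")

    @classmethod
    def empty(cls, like: LabelMask | ImageVolume) -> "LesionSet":
        return cls(
            union_mask=LabelMask(
                data=np.zeros(like.shape, dtype=np.uint8),
                spacing=like.spacing,
                origin=like.origin,
                label="lesions",
            )
        )


def _nearest_indices(mask: LabelMask, target, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Nearest source index for each target voxel centre on one axis.

    Tie rule: exact half-way points round up (floor(x + 0.5)), fixed so that
    the brute-force oracle and the implementation agree bit-for-bit.
    """
    centers = target.origin[axis] + np.arange(target.shape[axis]) * target.spacing[axis]
    pos = (centers - mask.origin[axis]) / mask.spacing[axis]
    idx = np.floor(pos + 0.5).astype(np.int64)
    valid = (idx >= 0) & (idx < mask.shape[axis])
    return np.clip(idx, 0, mask.shape[axis] - 1), valid


def resample_mask_to_grid(mask: LabelMask, target: ImageVolume | LabelMask) -> LabelMask:
    """Transfer a binary mask onto another grid by nearest-neighbor lookup.

    Each target voxel centre is mapped into source index space through the
    physical frame shared by the co-registered grids; voxels whose nearest
    source centre falls outside the source array are background.  Values
    remain strictly 0/1, and the operation is the identity when the grids
    coincide.
    """
    if min(target.shape) < 1:
        raise ValueError("degenerate target grid")
    if grids_equal(mask, target):
        return mask.with_data(mask.data.copy())
    ix, vx = _nearest_indices(mask, target, 0)
    iy, vy = _nearest_indices(mask, target, 1)
    iz, vz = _nearest_indices(mask, target, 2)
    out = mask.data[np.ix_(ix, iy, iz)].copy()
    out[~(vx[:, None, None] & vy[None, :, None] & vz[None, None, :])] = 0
    return LabelMask(
        data=out, spacing=target.spacing, origin=target.origin, label=mask.label
    )


def erode_mm(mask: LabelMask, radius: float) -> LabelMask:
    """Erode a binary mask by a physical margin in millimetres.

    A foreground voxel is kept iff its Euclidean distance to the nearest
    background voxel centre, measured with the grid's (possibly anisotropic)
    spacing, exceeds ``radius`` strictly.  Voxels beyond the array border are
    not treated as background.  Anti-extensive and monotone in the radius.
    """
    if radius < 0:
        raise ValueError("erosion radius must be nonnegative")
    if radius == 0 or mask.voxel_count() == 0:
        return mask.with_data(mask.data.copy())
    dist = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing)
    return mask.with_data((dist > radius).astype(np.uint8))


def remove_lesions(
    organ: LabelMask, lesions: LesionSet, margin_mm: float = 0.0
) -> LabelMask:
    """Excise tumor-lesion voxels from an organ mask.

    Voxelwise subtraction of the lesion union (``organ AND NOT lesions``).
    ``margin_mm`` optionally grows the lesion union by a metric margin before
    subtraction; the default 0 is the minimal reading of removing the lesion
    itself.  Never gains voxels; may return an empty mask, which downstream
    quantification flags rather than rejects.
    """
    lesion = lesions.union_mask
    if not grids_equal(organ, lesion):
        raise GridMismatchError("organ and lesion masks must share one grid")
    lesion_fg = lesion.data.astype(bool)
    if margin_mm > 0 and lesion_fg.any():
        dist_to_lesion = ndimage.distance_transform_edt(
            ~lesion_fg, sampling=lesion.spacing
        )
        lesion_fg = dist_to_lesion <= margin_mm
    out = organ.data.astype(bool) & ~lesion_fg
    return organ.with_data(out.astype(np.uint8))


def prepare_organ_masks(
    organs: OrganSet,
    lesions: LesionSet | None,
    pet: ImageVolume,
    margin_mm: float = 4.0,
    lesion_margin_mm: float = 0.0,
    erode_before_resample: bool = False,
) -> OrganSet:
    """Full organ-mask preparation: resample → erode → remove lesions.

    Organ masks (typically on the CT grid) are transferred to the PET grid,
    eroded by ``margin_mm``, and cleared of lesion voxels (lesion masks are
    expected natively on the PET grid).  ``erode_before_resample`` swaps the
    first two steps for sensitivity analyses.  Organs that end up empty are
    retained with empty masks so quantification can emit a flagged missing
    measurement instead of failing the whole patient.
    """
    if lesions is None:
        lesions = LesionSet.empty(pet)
    prepared: dict[str, LabelMask] = {}
    for name, mask in organs:
        if erode_before_resample:
            m = erode_mm(mask, margin_mm)
            m = resample_mask_to_grid(m, pet)
        else:
            m = resample_mask_to_grid(mask, pet)
            m = erode_mm(m, margin_mm)
        m = remove_lesions(m, lesions, margin_mm=lesion_margin_mm)
        prepared[name] = m
    return OrganSet(organs=prepared)
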