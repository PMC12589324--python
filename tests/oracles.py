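"""Independent reference computations used to check the implementation.

Each oracle deliberately takes a different route from the code it verifies:
erosion is checked with an all-pairs nearest-background distance query
(cKDTree over physical coordinates) instead of a distance transform;
resampling with a plain per-voxel Python loop; Fisher's exact test with an
exact integer enumeration of the conditional hypergeometric null; and the
gated location tests against R's ``stats`` package via ``Rscript``.
"""

from __future__ import annotations

import math
import subprocess
import tempfile
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree


def erode_by_distance_query(data: np.ndarray, spacing, radius: float) -> np.ndarray:
    """Keep foreground voxels whose min distance to background exceeds radius.

    Physical coordinates are voxel index × spacing; distances come from an
    exact nearest-neighbour query against all background voxel centres.
    """
    fg = np.argwhere(data > 0)
    bg = np.argwhere(data == 0)
    out = np.zeros_like(data, dtype=np.uint8)
    if fg.size == 0:
        return out
    if bg.size == 0:
        out[data > 0] = 1
        return out
    scale = np.asarray(spacing, dtype=float)
    dist, _ = cKDTree(bg * scale).query(fg * scale)
    keep = fg[dist > radius]
    out[tuple(keep.T)] = 1
    return out


def resample_nearest_loop(mask, target) -> np.ndarray:
    """Per-voxel coordinate-mapping loop; half-up tie rule floor(x + 0.5)."""
    out = np.zeros(target.shape, dtype=np.uint8)
    for i in range(target.shape[0]):
        for j in range(target.shape[1]):
            for k in range(target.shape[2]):
                src = []
                ok = True
                for ax, t in zip(range(3), (i, j, k)):
                    coord = target.origin[ax] + t * target.spacing[ax]
                    idx = math.floor((coord - mask.origin[ax]) / mask.spacing[ax] + 0.5)
                    if not (0 <= idx < mask.shape[ax]):
                        ok = False
                        break
                    src.append(idx)
                if ok:
                    out[i, j, k] = mask.data[tuple(src)]
    return out


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by integer hypergeometric enumeration.

    With margins fixed, the table probability is proportional to
    C(r1, k)·C(r2, c1−k); the two-sided p sums all tables at most as
    probable as the observed one (probability ties included, up to a 1e-12
    relative tolerance for float-boundary cases).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    obs = math.comb(r1, a) * math.comb(r2, c)
    num = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= obs or math.isclose(w, obs, rel_tol=1e-12):
            num += w
    return num / denom


def r_pvalue(expr: str, x, y) -> float:
    """Evaluate an R expression over vectors x and y and return its value."""
    with tempfile.NamedTemporaryFile("w", suffix=".R", delete=False) as f:
        f.write(f"x <- c({','.join(f'{float(v):.17g}' for v in x)})\n")
        f.write(f"y <- c({','.join(f'{float(v):.17g}' for v in y)})\n")
        f.write(f"cat(sprintf('%.15e', {expr}))\n")
        path = f.name
    try:
        out = subprocess.run(
            ["Rscript", "--vanilla", path], capture_output=True, text=True, timeout=120
        )
        if out.returncode != 0:
            raise RuntimeError(f"Rscript failed: {out.stderr}")
        return float(out.stdout.strip())
    finally:
        Path(path).unlink(missing_ok=True)


def random_blob_mask(rng: np.random.Generator, shape, spacing, n_seeds: int = 3):
    """A random blobby binary mask: union of random ellipsoids on the grid."""
    from petirae.volumes import LabelMask

    data = np.zeros(shape, dtype=bool)
    extent = [(s - 1) * sp for s, sp in zip(shape, spacing)]
    for _ in range(n_seeds):
        center = [rng.uniform(0.2 * e, 0.8 * e) for e in extent]
        semi = [rng.uniform(0.1 * e, 0.35 * e) for e in extent]
        axes = [
            (np.arange(shape[i]) * spacing[i] - center[i]) / semi[i] for i in range(3)
        ]
        data |= (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        ) <= 1.0
    return LabelMask(data=data.astype(np.uint8), spacing=tuple(spacing), origin=(0, 0, 0))
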