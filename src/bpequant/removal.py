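"""Electronic lesion removal by per-slice border-mean replacement.

On every slice that passes through the segmented lesion, the lesion pixels
are replaced by a single constant: the mean intensity of the pixels
bordering the lesion region on that slice.  The border ring is the
8-connected morphological dilation of the slice lesion region minus the
region itself, intersected with the image bounds; its width is configurable
(1 pixel by default).  No other voxel is touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fcm import LesionMask
from .volumes import SubtractionVolume

_RING_STRUCT = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass
class RemovalReport:
    n_slices_modified: int = 0
    fill_values: dict[int, float] = field(default_factory=dict)  # slice index -> fill
    n_voxels_replaced: int = 0
    warnings: list[str] = field(default_factory=list)


def border_ring(slice_mask: np.ndarray, ring_width: int = 1) -> np.ndarray:
    """8-connected dilation of a 2D region by ``ring_width`` minus the region."""
    dil = ndimage.binary_dilation(slice_mask, structure=_RING_STRUCT, iterations=ring_width)
    return dil & ~slice_mask


def remove_lesion(
    subvol: SubtractionVolume,
    lesion: LesionMask | np.ndarray,
    ring_width: int = 1,
) -> tuple[SubtractionVolume, RemovalReport]:
    """Return a copy of ``subvol`` with the lesion in-painted, plus a report.

    The fill value is computed from the same volume being edited.  If a
    slice's border ring is empty (the lesion fills the whole slice), the
    fill falls back to the volume-level border mean (3D dilation ring) and a
    warning is recorded in the report.
    """
    mask = lesion.mask_3d if isinstance(lesion, LesionMask) else np.asarray(lesion, dtype=bool)
    if mask.shape != subvol.shape:
        raise ValueError("lesion mask and volume are on different grids")
    out = subvol.data.copy()
    report = RemovalReport(n_voxels_replaced=int(mask.sum()))
    if not mask.any():
        return SubtractionVolume(out, subvol.time_point, subvol.spacing), report

    volume_fill: float | None = None
    for k in np.flatnonzero(mask.any(axis=(1, 2))):
        sl = mask[k]
        ring = border_ring(sl, ring_width)
        if ring.any():
            fill = float(subvol.data[k][ring].mean())
        else:
            if volume_fill is None:
                ring3d = ndimage.binary_dilation(
                    mask, structure=np.ones((3, 3, 3), dtype=bool), iterations=ring_width
                ) & ~mask
                volume_fill = float(subvol.data[ring3d].mean()) if ring3d.any() else 0.0
            fill = volume_fill
            msg = f"slice {k}: lesion fills the slice; used volume-level border mean"
            report.warnings.append(msg)
            warnings.warn(msg)
        out[k][sl] = fill
        report.fill_values[int(k)] = fill
        report.n_slices_modified += 1
    return SubtractionVolume(out, subvol.time_point, subvol.spacing), report


def removal_ratio(score_after: float, score_before: float) -> float:
    """Ratio of the BPE score after lesion removal to the score before."""
    if score_before <= 0:
        raise ZeroDivisionError("score before removal must be > 0 for a ratio")
    return score_after / score_before
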