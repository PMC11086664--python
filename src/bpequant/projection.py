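"""Maximum- and average-intensity projections of subtraction volumes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import SubtractionVolume

PROJECTION_TYPES = ("MIP", "AIP")


@dataclass
class ProjectionImage:
    """2D projection of a subtraction volume along the slice axis."""

    data: np.ndarray
    projection_type: str  # {MIP, AIP}
    time_point: int  # 1 or 2
    lesion_removed: bool = False


def project(
    subvol: SubtractionVolume,
    projection_type: str = "MIP",
    lesion_removed: bool = False,
) -> ProjectionImage:
    """Project along the slice axis: per-pixel max (MIP) or mean (AIP)."""
    if projection_type not in PROJECTION_TYPES:
        raise ValueError(f"projection_type must be one of {PROJECTION_TYPES}")
    if subvol.data.size == 0:
        raise ValueError("cannot project an empty volume")
    if projection_type == "MIP":
        img = subvol.data.max(axis=0)
    else:
        img = subvol.data.mean(axis=0)
    return ProjectionImage(
        data=img,
        projection_type=projection_type,
        time_point=subvol.time_point,
        lesion_removed=lesion_removed,
    )
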