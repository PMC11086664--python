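"""Computer BPE scores from projection images and breast masks.

A score is the mean pixel intensity of an 8-bit display version of a
projection image within one breast-region mask:

* the floating-point projection is windowed to [0, p] of the in-region
  intensity distribution (p = the in-region maximum by default, a lower
  percentile is configurable) and linearly quantized to 0-255 integers —
  the "original" image;
* the "rescaled" image maps the quantized image's own min-max range to
  [0, 1], mimicking per-image display normalization.

For lesion-removed variants both the 8-bit window and the rescale min-max
are taken from the matching before-removal image of the same region,
projection type and time point: removal edits the displayed image, so the
display mapping is held fixed.  This also makes the unaffected breast's
score bit-identical before and after removal, and keeps the after/before
score ratio at most 1 when the lesion is the brightest structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .breast_seg import BreastMasks
from .fcm import LesionMask
from .projection import ProjectionImage, project
from .removal import remove_lesion
from .volumes import DCEStudy, subtract

RESCALE_MODES = ("original", "rescaled")
REGIONS = ("both", "affected", "unaffected")

DEFAULT_WINDOW_PERCENTILE = 100.0


@dataclass
class ScoreRecord:
    exam_id: str
    region: str  # {both, affected, unaffected}
    projection_type: str  # {MIP, AIP}
    time_point: int  # 1 or 2
    rescale_mode: str  # {original, rescaled}
    lesion_removed: bool
    score: float
    rating: str | None = None


def quantize_to_8bit(
    values: np.ndarray,
    window: float | None = None,
    window_percentile: float = DEFAULT_WINDOW_PERCENTILE,
) -> tuple[np.ndarray, float]:
    """Window values to [0, window] and map linearly to 0-255 integers.

    When ``window`` is None it is set to the given percentile of ``values``.
    Returns the quantized array and the window used.
    """
    v = np.asarray(values, dtype=np.float64)
    if window is None:
        window = float(np.percentile(v, window_percentile))
    if window <= 0:
        return np.zeros(v.shape, dtype=np.uint8), 0.0
    q = np.rint(np.clip(v / window, 0.0, 1.0) * 255.0).astype(np.uint8)
    return q, window


def rescale_image(
    image: ProjectionImage | np.ndarray,
    mode: str = "rescaled",
    window: float | None = None,
    window_percentile: float = DEFAULT_WINDOW_PERCENTILE,
    minmax: tuple[float, float] | None = None,
    literal_divide_255: bool = False,
) -> np.ndarray:
    """8-bit display version of a projection image, original or rescaled.

    ``mode='original'`` returns the quantized 0-255 intensities as floats;
    ``mode='rescaled'`` additionally maps them to [0, 1]: by the image's own
    min-max range by default, by a caller-supplied ``minmax`` (used for
    lesion-removed variants, clipped to [0, 1]), or by a literal division by
    255 when ``literal_divide_255`` is set.  A constant image rescales to
    all zeros with a degenerate-range warning.
    """
    if mode not in RESCALE_MODES:
        raise ValueError(f"mode must be one of {RESCALE_MODES}")
    arr = image.data if isinstance(image, ProjectionImage) else np.asarray(image)
    q, _ = quantize_to_8bit(arr, window=window, window_percentile=window_percentile)
    qf = q.astype(np.float64)
    if mode == "original":
        return qf
    if literal_divide_255:
        return qf / 255.0
    if minmax is None:
        lo, hi = float(qf.min()), float(qf.max())
    else:
        lo, hi = minmax
    if hi <= lo:
        warnings.warn("degenerate intensity range; rescaled image set to zero")
        return np.zeros_like(qf)
    return np.clip((qf - lo) / (hi - lo), 0.0, 1.0)


def compute_score(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean pixel intensity within the mask (the computer BPE score)."""
    img = np.asarray(image, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if not m.any():
        raise ValueError("empty region mask; exam flagged")
    return float(img[m].mean())


def _region_scores(
    pix_before: np.ndarray,
    pix_after: np.ndarray,
    window_percentile: float,
) -> dict[tuple[str, bool], float]:
    """Scores for one (region, projection, time point) over modes x removal.

    The before-removal in-region pixel vector defines the 8-bit window and
    the rescale min-max shared by the after-removal variant.
    """
    qb, window = quantize_to_8bit(pix_before, window_percentile=window_percentile)
    qa, _ = quantize_to_8bit(pix_after, window=window)
    qbf, qaf = qb.astype(np.float64), qa.astype(np.float64)
    lo, hi = float(qbf.min()), float(qbf.max())
    out = {
        ("original", False): float(qbf.mean()),
        ("original", True): float(qaf.mean()),
    }
    if hi <= lo:
        warnings.warn("degenerate intensity range; rescaled scores set to zero")
        out[("rescaled", False)] = 0.0
        out[("rescaled", True)] = 0.0
    else:
        out[("rescaled", False)] = float(np.clip((qbf - lo) / (hi - lo), 0, 1).mean())
        out[("rescaled", True)] = float(np.clip((qaf - lo) / (hi - lo), 0, 1).mean())
    return out


def score_grid(
    study: DCEStudy,
    masks: BreastMasks,
    lesion: LesionMask | np.ndarray | None = None,
    ring_width: int = 1,
    window_percentile: float = DEFAULT_WINDOW_PERCENTILE,
    time_points: tuple[int, ...] = (1, 2),
    projection_types: tuple[str, ...] = ("MIP", "AIP"),
) -> list[ScoreRecord]:
    """Compute scores over the full combination grid for one exam.

    Grid: {both, affected, unaffected} x {MIP, AIP} x time points x
    {original, rescaled} x {before, after lesion removal}.  With no lesion
    (or an empty mask) the removal variants equal the before-removal scores.
    """
    lesion_arr = None
    if lesion is not None:
        lesion_arr = lesion.mask_3d if isinstance(lesion, LesionMask) else np.asarray(lesion, bool)
        if not lesion_arr.any():
            lesion_arr = None

    region_masks = {
        "both": np.asarray(masks.both, bool),
        "affected": np.asarray(masks.affected, bool),
        "unaffected": np.asarray(masks.unaffected, bool),
    }
    records: list[ScoreRecord] = []
    for tp in time_points:
        sub = subtract(study, tp)
        if lesion_arr is not None:
            sub_removed, _ = remove_lesion(sub, lesion_arr, ring_width=ring_width)
        else:
            sub_removed = sub
        for ptype in projection_types:
            proj_b = project(sub, ptype)
            proj_a = project(sub_removed, ptype, lesion_removed=True)
            for region, rmask in region_masks.items():
                if not rmask.any():
                    warnings.warn(f"empty {region} mask for exam {study.exam_id}; records skipped")
                    continue
                scores = _region_scores(
                    proj_b.data[rmask], proj_a.data[rmask], window_percentile
                )
                for (mode, removed), score in scores.items():
                    records.append(ScoreRecord(
                        exam_id=study.exam_id,
                        region=region,
                        projection_type=ptype,
                        time_point=tp,
                        rescale_mode=mode,
                        lesion_removed=removed,
                        score=score,
                        rating=study.rating,
                    ))
    return records
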