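"""Whole-breast segmentation on second post-contrast subtraction MIPs.

A small trainable U-Net produces a pixel probability map; post-processing
thresholds it at 0.25, keeps the largest 8-connected object (the region
containing both breasts, holes filled) and splits it vertically at the
centre of its bounding box into affected and unaffected breast masks.

A non-learned fallback segmenter (Otsu threshold + largest component +
hole filling) is provided so the pipeline can run without a training step;
it is a convenience, not the reference method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .projection import ProjectionImage
from .unet import UNet, train_unet

DEFAULT_THRESHOLD = 0.25

_STRUCT8 = np.ones((3, 3), dtype=bool)


class EmptyMaskError(ValueError):
    """No pixel exceeded the probability threshold; exam is unsegmentable."""


@dataclass
class ProbabilityMap:
    data: np.ndarray  # 2D, values in [0, 1]


@dataclass
class BreastMasks:
    both: np.ndarray
    affected: np.ndarray
    unaffected: np.ndarray
    split_column: int
    sides_labeled: bool = True  # False when affected side unknown (left/right only)


@dataclass
class BreastSegmenter:
    """Trained segmentation model plus the shape it was trained at."""

    model: UNet
    input_shape: tuple[int, int]
    final_loss: float
    losses: list[float]

    def save(self, path: str | Path) -> None:
        self.model.save(path)

    @classmethod
    def load(cls, path: str | Path, input_shape: tuple[int, int] = (128, 128)) -> "BreastSegmenter":
        model = UNet.load(path)
        return cls(model=model, input_shape=input_shape, final_loss=float("nan"), losses=[])


def _normalize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float32)
    peak = float(img.max())
    return img / peak if peak > 0 else img


def train_segmenter(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    epochs_max: int = 30,
    seed: int = 0,
    input_shape: tuple[int, int] = (128, 128),
    base_width: int = 8,
    lr: float = 2e-3,
) -> BreastSegmenter:
    """Train the U-Net on (MIP image, reference breast mask) pairs.

    Images are max-normalized and resized to ``input_shape``; training uses
    Adam with a binary cross-entropy loss, for at most ``epochs_max`` epochs.
    Pairs with an empty reference mask are rejected with a warning; fewer
    than 8 usable pairs triggers an insufficient-data warning but training
    still runs.
    """
    usable_imgs, usable_masks = [], []
    for i, (img, mask) in enumerate(pairs):
        if not np.asarray(mask).any():
            warnings.warn(f"training pair {i} has an empty reference mask; skipped")
            continue
        im = resize(_normalize(img), input_shape, order=1, anti_aliasing=True)
        mk = resize(np.asarray(mask, dtype=float), input_shape, order=0) > 0.5
        usable_imgs.append(im.astype(np.float32))
        usable_masks.append(mk.astype(np.float32))
    if not usable_imgs:
        raise ValueError("no usable training pairs")
    if len(usable_imgs) < 8:
        warnings.warn(f"only {len(usable_imgs)} training pairs; segmentation may be unreliable")
    model, losses = train_unet(
        np.stack(usable_imgs), np.stack(usable_masks),
        epochs=epochs_max, seed=seed, base_width=base_width, lr=lr,
    )
    return BreastSegmenter(model=model, input_shape=input_shape,
                           final_loss=losses[-1], losses=losses)


def predict_probability(segmenter: BreastSegmenter, mip: ProjectionImage | np.ndarray) -> ProbabilityMap:
    """Pixel probability map in [0,1], same shape as the input image."""
    img = mip.data if isinstance(mip, ProjectionImage) else np.asarray(mip)
    native_shape = img.shape
    x = resize(_normalize(img), segmenter.input_shape, order=1, anti_aliasing=True)
    prob = segmenter.model.predict(x[None, None].astype(np.float32))[0, 0]
    if native_shape != segmenter.input_shape:
        prob = resize(prob, native_shape, order=1)
    return ProbabilityMap(data=np.clip(prob, 0.0, 1.0))


def postprocess_mask(prob: ProbabilityMap | np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Threshold the probability map and keep the largest object, holes filled.

    Raises :class:`EmptyMaskError` when no pixel exceeds the threshold.
    """
    p = prob.data if isinstance(prob, ProbabilityMap) else np.asarray(prob)
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    binary = p > threshold
    if not binary.any():
        raise EmptyMaskError("no pixel above threshold; exam flagged unsegmentable")
    labels, n = ndimage.label(binary, structure=_STRUCT8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def split_breasts(both_mask: np.ndarray, affected_side: str = "unknown",
                  mode: str = "bbox") -> BreastMasks:
    """Vertically split the both-breast mask at its centre into two sides.

    ``mode='bbox'`` (default) splits at the horizontal centre of the mask's
    bounding box; ``mode='centroid'`` splits at the mask centroid column.
    Columns left of the split form the image-left breast.  If
    ``affected_side`` is unknown the masks are labeled left/right only
    (affected = left by position, ``sides_labeled=False``).
    """
    both = np.asarray(both_mask, dtype=bool)
    if not both.any():
        raise ValueError("empty breast mask")
    cols = np.nonzero(both.any(axis=0))[0]
    if mode == "bbox":
        c0, c1 = int(cols.min()), int(cols.max())
        split = c0 + (c1 - c0 + 1) // 2
    elif mode == "centroid":
        split = int(round(float(ndimage.center_of_mass(both)[1])))
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    left = both.copy()
    left[:, split:] = False
    right = both & ~left
    if affected_side == "left":
        affected, unaffected = left, right
    elif affected_side == "right":
        affected, unaffected = right, left
    else:
        warnings.warn("affected side unknown; masks labeled by position only")
        return BreastMasks(both=both, affected=left, unaffected=right,
                           split_column=split, sides_labeled=False)
    return BreastMasks(both=both, affected=affected, unaffected=unaffected,
                       split_column=split)


def fallback_segmenter(mip: ProjectionImage | np.ndarray) -> ProbabilityMap:
    """Non-learned stand-in probability map: Otsu foreground as {0,1} map.

    Convenience so the pipeline runs without training; the learned U-Net is
    the reference route.
    """
    img = mip.data if isinstance(mip, ProjectionImage) else np.asarray(mip)
    finite = np.asarray(img, dtype=float)
    if np.ptp(finite) <= 0:
        return ProbabilityMap(data=np.zeros_like(finite))
    thr = threshold_otsu(finite)
    return ProbabilityMap(data=(finite > thr).astype(float))
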