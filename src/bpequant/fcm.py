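"""3D lesion segmentation by fuzzy c-means (FCM) clustering.

FCM assigns each voxel a fractional membership in each of ``c`` intensity
clusters by minimising the fuzzified within-cluster objective

    J = sum_k sum_i  u_ik^m * |x_k - v_i|^2

with the alternating update scheme:

    u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1)),    v_i = sum_k u_ik^m x_k / sum_k u_ik^m.

The lesion class is the cluster with the highest centre intensity; voxels
whose lesion-class membership exceeds a threshold are candidates, from
which the largest 26-connected component (with slice-wise hole filling)
becomes the lesion mask.  The lesion size metric is the square root of the
lesion area on the centre lesion slice (the slice of maximal area).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import SubtractionVolume


class DegenerateInputError(ValueError):
    """Fewer distinct intensity values than requested clusters."""


@dataclass
class FCMResult:
    membership: np.ndarray  # (n_samples, c), rows sum to 1
    centers: np.ndarray  # (c,) sorted ascending
    n_iterations: int
    converged: bool
    objective: list[float]  # objective value per iteration

    @property
    def lesion_class(self) -> int:
        """Index of the cluster with the highest centre intensity."""
        return int(np.argmax(self.centers))


@dataclass
class LesionMask:
    mask_3d: np.ndarray
    size_mm: float
    center_slice_index: int

    @property
    def n_voxels(self) -> int:
        return int(self.mask_3d.sum())


def _memberships(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    # u_ik = 1 / sum_j (d_ik/d_jk)^(2/(m-1)); distances are floored so a voxel
    # coincident with a centre gets (essentially) full membership there
    d = np.maximum(np.abs(x[:, None] - centers[None, :]), 1e-12)
    inv = d ** (-2.0 / (m - 1.0))
    return inv / inv.sum(axis=1, keepdims=True)


def fcm_cluster(
    values: np.ndarray,
    c: int = 2,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = None,
    init: str = "extrema",
) -> FCMResult:
    """Cluster 1D intensities into ``c`` fuzzy classes.

    ``init='extrema'`` (default) places initial centres at evenly spaced
    quantile positions between the minimum and maximum intensity, which is
    deterministic; ``init='random'`` samples centres from the data using
    ``seed``.  Convergence is declared when the maximum centre shift falls
    below ``tol``.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if m <= 1:
        raise ValueError("fuzziness exponent m must be > 1")
    if np.unique(x).size < c:
        raise DegenerateInputError(
            f"need at least {c} distinct values, got {np.unique(x).size}"
        )
    if init == "extrema":
        centers = np.linspace(x.min(), x.max(), c)
    elif init == "random":
        rng = np.random.default_rng(seed)
        centers = np.sort(rng.choice(np.unique(x), size=c, replace=False).astype(float))
    else:
        raise ValueError(f"unknown init {init!r}")

    objective: list[float] = []
    converged = False
    n_it = 0
    for n_it in range(1, max_iter + 1):
        u = _memberships(x, centers, m)
        um = u**m
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        d2 = (x[:, None] - new_centers[None, :]) ** 2
        objective.append(float((um * d2).sum()))
        shift = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if shift < tol:
            converged = True
            break
    u = _memberships(x, centers, m)
    order = np.argsort(centers)
    return FCMResult(
        membership=u[:, order],
        centers=centers[order],
        n_iterations=n_it,
        converged=converged,
        objective=objective,
    )


def segment_lesion(
    subvol: SubtractionVolume,
    roi: tuple[slice, slice, slice],
    c: int = 3,
    m: float = 2.0,
    membership_threshold: float = 0.5,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = None,
) -> LesionMask:
    """Segment the enhancing lesion inside a region-of-interest box.

    FCM is run on the ROI subtraction intensities; voxels with lesion-class
    membership above ``membership_threshold`` are candidates.  The default
    ``c=3`` reflects the three intensity classes a lesion ROI contains on a
    subtraction volume (fat, enhancing parenchyma, lesion); with ``c=2``
    the parenchyma merges into the lesion class.  The largest
    26-connected candidate component, hole-filled slice by slice, is the
    lesion.  An empty candidate set yields an empty mask with a warning
    rather than an exception.
    """
    sub = subvol.data[roi]
    if sub.size == 0:
        raise ValueError("ROI contains no voxels")
    full_mask = np.zeros(subvol.shape, dtype=bool)
    try:
        res = fcm_cluster(sub.ravel(), c=c, m=m, tol=tol, max_iter=max_iter, seed=seed)
    except DegenerateInputError:
        warnings.warn("ROI intensities degenerate; returning empty lesion mask")
        return LesionMask(mask_3d=full_mask, size_mm=0.0, center_slice_index=-1)

    cand = (res.membership[:, res.lesion_class] > membership_threshold).reshape(sub.shape)
    if not cand.any():
        warnings.warn("no voxel exceeded the lesion membership threshold; empty mask")
        return LesionMask(mask_3d=full_mask, size_mm=0.0, center_slice_index=-1)

    labels, n = ndimage.label(cand, structure=np.ones((3, 3, 3), dtype=bool))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    comp = labels == (1 + int(np.argmax(sizes)))
    for k in range(comp.shape[0]):  # slice-wise hole filling
        comp[k] = ndimage.binary_fill_holes(comp[k])

    full_mask[roi] = comp
    lm = LesionMask(mask_3d=full_mask, size_mm=0.0, center_slice_index=-1)
    lm.size_mm, lm.center_slice_index = _size_and_center(full_mask, subvol.spacing)
    return lm


def _size_and_center(mask: np.ndarray, spacing) -> tuple[float, int]:
    areas = mask.sum(axis=(1, 2))
    center = int(np.argmax(areas))  # ties -> lower slice index
    area_mm2 = float(areas[center]) * spacing[1] * spacing[2]
    return float(np.sqrt(area_mm2)), center


def lesion_size(mask: LesionMask | np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Lesion size in mm: sqrt of the lesion area on the centre lesion slice.

    The centre slice is the slice of maximal lesion area (ties broken toward
    the lower slice index).  An empty mask yields 0 with a warning.
    """
    arr = mask.mask_3d if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)
    if not arr.any():
        warnings.warn("empty lesion mask; size is 0")
        return 0.0
    size, _ = _size_and_center(arr, spacing)
    return size
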