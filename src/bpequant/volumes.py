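"""Exam-level data model, volume I/O and subtraction-image construction.

Axis convention used throughout the package: axis 0 is the slice
(through-plane) axis, axes 1-2 are in-plane rows x columns.  Projections
collapse axis 0, so a projection image shows both breasts side by side.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

BPE_LEVELS = ("minimal", "mild", "moderate", "marked")

#: ordinal code for each BPE level, 1 = minimal .. 4 = marked
BPE_LEVEL_CODE = {name: i + 1 for i, name in enumerate(BPE_LEVELS)}


class GridMismatchError(ValueError):
    """Volumes of one exam do not share a common grid."""


@dataclass
class DCEStudy:
    """One DCE-MRI exam: a pre-contrast volume plus >= 2 post-contrast volumes.

    ``posts[0]`` is the first post-contrast volume, ``posts[1]`` the second.
    All volumes share one grid shape and one voxel spacing.
    """

    exam_id: str
    pre: np.ndarray
    posts: list[np.ndarray]
    voxel_spacing_mm: tuple[float, float, float]
    affected_side: str = "unknown"  # {left, right, unknown}
    rating: str | None = None  # ordinal BPE level or None

    def __post_init__(self) -> None:
        shapes = {self.pre.shape} | {p.shape for p in self.posts}
        if len(shapes) != 1:
            raise GridMismatchError(
                f"exam {self.exam_id}: volumes have mixed shapes {sorted(shapes)}"
            )
        if self.rating is not None and self.rating not in BPE_LEVELS:
            raise ValueError(f"unknown BPE rating {self.rating!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pre.shape

    @property
    def n_post(self) -> int:
        return len(self.posts)


@dataclass
class SubtractionVolume:
    """Post-contrast minus pre-contrast volume (clipped at 0 by default)."""

    data: np.ndarray
    time_point: int  # 1 = first post-contrast, 2 = second
    spacing: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def subtract(study: DCEStudy, time_point: int, clip_negative: bool = True) -> SubtractionVolume:
    """Build the subtraction volume ``post_t - pre`` for time point ``t``.

    Negative differences are clipped to zero by default: MIPs are unaffected,
    and without clipping AIP values would be pulled down by noise in fat.
    Set ``clip_negative=False`` for signed subtraction values.
    """
    if not (1 <= time_point <= study.n_post):
        raise ValueError(
            f"time point {time_point} not available; study has post-contrast "
            f"points {list(range(1, study.n_post + 1))}"
        )
    diff = study.posts[time_point - 1].astype(np.float64) - study.pre.astype(np.float64)
    if clip_negative:
        diff = np.clip(diff, 0.0, None)
    return SubtractionVolume(data=diff, time_point=time_point, spacing=study.voxel_spacing_mm)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _spacing_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # array axes are (slice, row, col); store spacing on the matching axes
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


def write_nifti(path: str | os.PathLike, data: np.ndarray,
                spacing: tuple[float, float, float]) -> Path:
    import nibabel as nib

    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), _spacing_affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))
    return path


def read_nifti(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cannot read volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


# ---------------------------------------------------------------------------
# Minimal DICOM series I/O (one file per slice)
# ---------------------------------------------------------------------------


def write_dicom_series(dirpath: str | os.PathLike, data: np.ndarray,
                       spacing: tuple[float, float, float],
                       series_description: str = "phantom") -> Path:
    """Write an integer-valued volume as an uncompressed DICOM series.

    One secondary-capture file per slice, slice order encoded in
    InstanceNumber and ImagePositionPatient.  Intended for phantom export
    and round-trip testing, not for clinical interchange.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("DICOM export requires an integer-valued volume")
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("DICOM export supports values in [0, 65535]")
    arr = arr.astype(np.uint16)

    series_uid = generate_uid()
    study_uid = generate_uid()
    for i, sl in enumerate(arr):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.SeriesDescription = series_description
        ds.Modality = "MR"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * spacing[0]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [spacing[1], spacing[2]]
        ds.SliceThickness = spacing[0]
        ds.SpacingBetweenSlices = spacing[0]
        ds.Rows, ds.Columns = sl.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = sl.tobytes()
        ds.save_as(str(dirpath / f"slice_{i:04d}.dcm"), enforce_file_format=True)
    return dirpath


def read_dicom_series(dirpath: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    import pydicom

    dirpath = Path(dirpath)
    files = sorted(dirpath.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {dirpath}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda ds: int(ds.InstanceNumber))
    slices = [ds.pixel_array for ds in datasets]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise GridMismatchError(f"DICOM series {dirpath} has mixed slice shapes {sorted(shapes)}")
    ds0 = datasets[0]
    spacing = (
        float(getattr(ds0, "SpacingBetweenSlices", getattr(ds0, "SliceThickness", 1.0))),
        float(ds0.PixelSpacing[0]),
        float(ds0.PixelSpacing[1]),
    )
    return np.stack(slices, axis=0), spacing


def _load_volume(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    return read_nifti(path)


def load_study(
    paths: Sequence[str | os.PathLike],
    exam_id: str = "exam",
    affected_side: str = "unknown",
    rating: str | None = None,
) -> DCEStudy:
    """Load an exam from per-time-point volume paths (pre, post1, post2, ...).

    Each path is either a NIfTI file or a DICOM series directory.  The order
    of ``paths`` defines the time-point order.  All volumes must share one
    grid shape; mismatching spacings raise :class:`GridMismatchError`.
    """
    if len(paths) < 2:
        raise ValueError("need at least a pre-contrast and one post-contrast volume")
    vols, spacings = [], []
    for p in paths:
        data, spacing = _load_volume(p)
        vols.append(data)
        spacings.append(tuple(round(s, 6) for s in spacing))
    if len(set(spacings)) != 1:
        raise GridMismatchError(f"volumes of exam {exam_id} have mixed spacings {sorted(set(spacings))}")
    return DCEStudy(
        exam_id=exam_id,
        pre=vols[0],
        posts=vols[1:],
        voxel_spacing_mm=spacings[0],
        affected_side=affected_side,
        rating=rating,
    )
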