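"""Synthetic bilateral-breast DCE-MRI phantom with known BPE level and lesion.

The phantom emulates the image features the scoring pipeline depends on,
without simulating pharmacokinetics:

* two half-ellipsoid breasts anterior to a flat chest-wall band, meeting
  near the midline so the projected both-breast region is one connected
  component (as required by the largest-object / vertical-split logic);
* fibroglandular tissue (FGT) modelled as a smoothed random blob field
  thresholded to a target fraction of breast volume; the *enhancing* subset
  of FGT is the top quantile of the same field, so enhancing sets are
  nested across BPE levels;
* a thin enhancing skin rim on the curved breast surface, which is what
  outlines the breast on real subtraction MIPs;
* an optional hyper-enhancing spherical lesion in one breast;
* additive Gaussian noise, clipped at zero.

Intensity over the dynamic series is ``base + amplitude * uptake(t)``;
the uptake curve is monotone in the post-contrast index, lesions enhance
faster and ``amplitude_lesion = amplitude_fgt * lesion_contrast_multiplier``.
The four clinical BPE levels map to a strictly increasing pair of
(enhancement amplitude, enhancing-FGT fraction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes import BPE_LEVELS, DCEStudy, write_nifti

#: full enhancement dynamic range (arbitrary intensity units)
DYNAMIC_RANGE = 200.0

#: BPE level -> fraction of the lesion-free dynamic range used as FGT amplitude
LEVEL_AMPLITUDE_FRACTION = {
    "minimal": 0.10,
    "mild": 0.25,
    "moderate": 0.45,
    "marked": 0.70,
}

#: BPE level -> fraction of FGT voxels that enhance
LEVEL_ENHANCING_FRACTION = {
    "minimal": 0.15,
    "mild": 0.40,
    "moderate": 0.70,
    "marked": 0.95,
}

#: uptake multipliers at (first, second) post-contrast time points
FGT_UPTAKE = (0.65, 1.0)
LESION_UPTAKE = (0.95, 1.0)

# base (pre-contrast) tissue intensities
BASE_FAT = 60.0
BASE_FGT = 50.0
BASE_SKIN = 55.0
BASE_CHEST = 40.0
BASE_LESION = 50.0

SKIN_AMPLITUDE = 20.0
CHEST_AMPLITUDE = 6.0


class PhantomSizingError(ValueError):
    """Requested lesion does not fit inside the breast."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic exam."""

    grid_shape: tuple[int, int, int] = (24, 128, 128)
    voxel_spacing_mm: tuple[float, float, float] = (3.0, 1.5, 1.5)
    bpe_level: str = "mild"
    fgt_fraction: float = 0.35
    lesion_diameter_mm: float = 0.0
    lesion_side: str = "none"  # {left, right, none}
    lesion_contrast_multiplier: float = 3.0
    noise_sd: float = 1.0
    n_post: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bpe_level not in BPE_LEVELS:
            raise ValueError(f"unknown BPE level {self.bpe_level!r}")
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("each grid axis must have at least 16 voxels")
        if not (0.0 < self.fgt_fraction < 1.0):
            raise ValueError("fgt_fraction must be in (0, 1)")
        if (self.lesion_diameter_mm == 0) != (self.lesion_side == "none"):
            raise ValueError("lesion_diameter_mm must be 0 iff lesion_side is 'none'")
        if self.lesion_side not in ("left", "right", "none"):
            raise ValueError(f"unknown lesion_side {self.lesion_side!r}")
        if self.lesion_contrast_multiplier < 1.0:
            raise ValueError("lesion_contrast_multiplier must be >= 1")
        if self.n_post < 2:
            raise ValueError("need at least two post-contrast time points")


@dataclass
class PhantomTruth:
    """Ground-truth masks and programmed level of one phantom exam."""

    breast_mask_3d: np.ndarray
    left_mask_3d: np.ndarray
    right_mask_3d: np.ndarray
    fgt_mask_3d: np.ndarray
    lesion_mask_3d: np.ndarray
    true_bpe_level: str

    def breast_projection_mask(self) -> np.ndarray:
        """2D both-breast mask as seen in a projection (max over slices)."""
        return self.breast_mask_3d.any(axis=0)


def _geometry(spec: PhantomSpec):
    """Scaled-radius fields and tissue masks for the fixed two-breast anatomy."""
    ns, nr, nc = spec.grid_shape
    ds, dr, dc = spec.voxel_spacing_mm
    s_mm = np.arange(ns)[:, None, None] * ds
    r_mm = np.arange(nr)[None, :, None] * dr
    c_mm = np.arange(nc)[None, None, :] * dc
    width_mm = nc * dc
    depth_mm = ns * ds

    chest_wall_mm = 30.0
    semi_s = min(30.0, 0.45 * depth_mm)
    semi_r = min(60.0, 0.6 * (nr * dr - chest_wall_mm))
    semi_c = 0.24 * width_mm
    center_s = (ns - 1) * ds / 2.0
    offsets = 0.22 * width_mm  # breast centres at midline -/+ offsets
    mid_mm = width_mm / 2.0

    rho = {}
    for side, cc in (("left", mid_mm - offsets), ("right", mid_mm + offsets)):
        rho[side] = np.sqrt(
            ((s_mm - center_s) / semi_s) ** 2
            + ((r_mm - chest_wall_mm) / semi_r) ** 2
            + ((c_mm - cc) / semi_c) ** 2
        )
    anterior = np.broadcast_to(r_mm >= chest_wall_mm, spec.grid_shape)
    side_masks = {side: (rho[side] <= 1.0) & anterior for side in rho}
    breast = side_masks["left"] | side_masks["right"]

    # thin enhancing skin rim on the curved surface, limited in through-slice
    # extent so the projected rim is an outline, not a filled disc
    slab = np.broadcast_to(np.abs(s_mm - center_s) <= 0.35 * semi_s, spec.grid_shape)
    skin = np.zeros(spec.grid_shape, dtype=bool)
    inner = np.zeros(spec.grid_shape, dtype=bool)
    for side in rho:
        skin |= (rho[side] >= 0.93) & side_masks[side] & slab
        inner |= (rho[side] <= 0.85) & side_masks[side]
    chest = np.broadcast_to(r_mm < chest_wall_mm, spec.grid_shape).copy()

    geo = {
        "rho": rho,
        "breast": breast,
        "side_masks": side_masks,
        "skin": skin,
        "inner": inner,
        "chest": chest,
        "centers_mm": {
            "left": (center_s, chest_wall_mm + 0.45 * semi_r, mid_mm - offsets),
            "right": (center_s, chest_wall_mm + 0.45 * semi_r, mid_mm + offsets),
        },
        "mid_col": int(np.ceil(mid_mm / dc)),
        "coords_mm": (s_mm, r_mm, c_mm),
    }
    return geo


def _lesion_mask(spec: PhantomSpec, geo) -> np.ndarray:
    if spec.lesion_side == "none":
        return np.zeros(spec.grid_shape, dtype=bool)
    s_mm, r_mm, c_mm = geo["coords_mm"]
    cs, cr, cc = geo["centers_mm"][spec.lesion_side]
    r = spec.lesion_diameter_mm / 2.0
    dist = np.sqrt((s_mm - cs) ** 2 + (r_mm - cr) ** 2 + (c_mm - cc) ** 2)
    mask = dist <= r
    rho = geo["rho"][spec.lesion_side]
    if not mask.any() or (mask & ((rho > 0.95) | geo["chest"])).any():
        raise PhantomSizingError(
            f"lesion of diameter {spec.lesion_diameter_mm} mm does not fit "
            f"inside the {spec.lesion_side} breast"
        )
    return mask


def generate_study(spec: PhantomSpec) -> tuple[DCEStudy, PhantomTruth]:
    """Generate one phantom exam and its ground truth.

    Deterministic: identical spec (including seed) yields bit-identical
    volumes.  Raises :class:`PhantomSizingError` when the requested lesion
    does not fit in the breast.
    """
    rng = np.random.default_rng(spec.seed)
    geo = _geometry(spec)
    breast, inner, skin, chest = geo["breast"], geo["inner"], geo["skin"], geo["chest"]
    lesion = _lesion_mask(spec, geo)

    # FGT blob field: smoothed white noise, thresholded within the inner
    # breast so that |FGT| = fgt_fraction * |breast|
    blob = gaussian_filter(
        rng.standard_normal(spec.grid_shape).astype(np.float32), sigma=(1.2, 3.0, 3.0)
    )
    fgt_region = inner & ~skin & ~lesion
    n_target = int(round(spec.fgt_fraction * breast.sum()))
    n_target = min(n_target, int(fgt_region.sum()))
    vals = blob[fgt_region]
    thr = np.sort(vals)[-n_target] if n_target > 0 else np.inf
    fgt = fgt_region & (blob >= thr)

    # nested enhancing subset: top LEVEL_ENHANCING_FRACTION of FGT by blob value
    enh_frac = LEVEL_ENHANCING_FRACTION[spec.bpe_level]
    n_enh = int(round(enh_frac * fgt.sum()))
    fvals = blob[fgt]
    ethr = np.sort(fvals)[-n_enh] if n_enh > 0 else np.inf
    enhancing = fgt & (blob >= ethr)

    amp_fgt = LEVEL_AMPLITUDE_FRACTION[spec.bpe_level] * DYNAMIC_RANGE

    base = np.zeros(spec.grid_shape, dtype=np.float32)
    base[chest] = BASE_CHEST
    base[breast] = BASE_FAT
    base[skin] = BASE_SKIN
    base[fgt] = BASE_FGT
    base[lesion] = BASE_LESION

    amp = np.zeros(spec.grid_shape, dtype=np.float32)
    amp[chest] = CHEST_AMPLITUDE
    amp[enhancing] = amp_fgt
    amp[skin] = SKIN_AMPLITUDE
    amp[lesion] = amp_fgt * spec.lesion_contrast_multiplier

    uptake_slow = np.concatenate([[0.0], np.asarray(FGT_UPTAKE)])
    uptake_fast = np.concatenate([[0.0], np.asarray(LESION_UPTAKE)])
    if spec.n_post > 2:  # extend monotonically past the modelled two points
        extra = 1.0 + 0.05 * np.arange(1, spec.n_post - 1)
        uptake_slow = np.concatenate([uptake_slow, extra])
        uptake_fast = np.concatenate([uptake_fast, extra])

    vols = []
    for t in range(spec.n_post + 1):
        u = np.full(spec.grid_shape, uptake_slow[t], dtype=np.float32)
        u[lesion] = uptake_fast[t]
        vol = base + amp * u
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, spec.grid_shape).astype(np.float32)
        vols.append(np.clip(vol, 0.0, None).astype(np.float32))

    mid = geo["mid_col"]
    left = breast.copy()
    left[:, :, mid:] = False
    right = breast & ~left

    study = DCEStudy(
        exam_id=f"phantom-{spec.seed}",
        pre=vols[0],
        posts=vols[1:],
        voxel_spacing_mm=spec.voxel_spacing_mm,
        affected_side=spec.lesion_side if spec.lesion_side != "none" else "unknown",
        rating=spec.bpe_level,
    )
    truth = PhantomTruth(
        breast_mask_3d=breast,
        left_mask_3d=left,
        right_mask_3d=right,
        fgt_mask_3d=fgt,
        lesion_mask_3d=lesion,
        true_bpe_level=spec.bpe_level,
    )
    return study, truth


def lesion_roi_from_truth(truth: PhantomTruth, pad: int = 8) -> tuple[slice, slice, slice] | None:
    """Padded bounding box of the true lesion, as slice objects (or None).

    Stands in for the manifest-supplied region of interest around the
    clinically diagnosed lesion.
    """
    if not truth.lesion_mask_3d.any():
        return None
    idx = np.nonzero(truth.lesion_mask_3d)
    roi = []
    for ax, ind in enumerate(idx):
        lo = max(int(ind.min()) - pad, 0)
        hi = min(int(ind.max()) + 1 + pad, truth.lesion_mask_3d.shape[ax])
        roi.append(slice(lo, hi))
    return tuple(roi)


def generate_cohort(
    n: int,
    level_distribution: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    lesion_diameter_range_mm: tuple[float, float] = (4.0, 30.0),
    spec_template: PhantomSpec | None = None,
) -> tuple[list[tuple[DCEStudy, PhantomTruth]], dict[str, int]]:
    """Generate a cohort of phantom exams with programmed BPE levels.

    Levels are drawn from ``level_distribution``; per-study seeds are derived
    deterministically from the cohort ``seed``.  Every exam receives one
    lesion with diameter uniform in ``lesion_diameter_range_mm`` on a random
    side (set the range to ``(0, 0)`` for lesion-free exams).  Returns the
    studies with their truths plus the realized level counts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    probs = np.asarray(level_distribution, dtype=float)
    if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValueError("level_distribution must be 4 non-negative probabilities summing to 1")

    template = spec_template or PhantomSpec()
    rng = np.random.default_rng(seed)
    levels = rng.choice(len(BPE_LEVELS), size=n, p=probs)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]

    out: list[tuple[DCEStudy, PhantomTruth]] = []
    counts = {lev: 0 for lev in BPE_LEVELS}
    lo, hi = lesion_diameter_range_mm
    for i in range(n):
        level = BPE_LEVELS[int(levels[i])]
        counts[level] += 1
        if hi > 0:
            diam = float(rng.uniform(lo, hi))
            side = "left" if rng.random() < 0.5 else "right"
        else:
            diam, side = 0.0, "none"
        spec = PhantomSpec(
            grid_shape=template.grid_shape,
            voxel_spacing_mm=template.voxel_spacing_mm,
            bpe_level=level,
            fgt_fraction=template.fgt_fraction,
            lesion_diameter_mm=diam,
            lesion_side=side,
            lesion_contrast_multiplier=template.lesion_contrast_multiplier,
            noise_sd=template.noise_sd,
            n_post=template.n_post,
            seed=child_seeds[i],
        )
        study, truth = generate_study(spec)
        study.exam_id = f"phantom-{i:03d}"
        out.append((study, truth))
    return out, counts


def export_study(study: DCEStudy, truth: PhantomTruth, outdir: str | Path,
                 spec: PhantomSpec | None = None) -> dict:
    """Write one phantom exam as NIfTI volumes + truth masks + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = study.voxel_spacing_mm
    paths = {"pre": str(write_nifti(outdir / "pre.nii.gz", study.pre, sp))}
    for i, post in enumerate(study.posts, start=1):
        paths[f"post{i}"] = str(write_nifti(outdir / f"post{i}.nii.gz", post, sp))
    for name, mask in [
        ("breast_mask", truth.breast_mask_3d),
        ("left_mask", truth.left_mask_3d),
        ("right_mask", truth.right_mask_3d),
        ("fgt_mask", truth.fgt_mask_3d),
        ("lesion_mask", truth.lesion_mask_3d),
    ]:
        paths[name] = str(write_nifti(outdir / f"{name}.nii.gz", mask.astype(np.uint8), sp))
    sidecar = {"exam_id": study.exam_id, "true_bpe_level": truth.true_bpe_level,
               "affected_side": study.affected_side, "paths": paths}
    if spec is not None:
        sidecar["spec"] = asdict(spec)
    (outdir / "phantom.json").write_text(json.dumps(sidecar, indent=2))
    return sidecar
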