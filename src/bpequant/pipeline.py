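"""End-to-end orchestration: per-exam pipeline, cohort runs and evaluation.

``run_exam`` executes subtraction -> lesion segmentation -> electronic
lesion removal -> projection -> breast masking -> score grid for one exam;
``run_cohort`` maps it over a cohort with failure isolation and then runs
the statistical evaluation (tau-b and both ROC tasks per image variant,
plus the after/before ratio versus lesion size).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .breast_seg import (
    BreastSegmenter,
    fallback_segmenter,
    postprocess_mask,
    predict_probability,
    split_breasts,
)
from .evaluation import (
    TASKS,
    dichotomize,
    kendall_tau_b,
    ratio_vs_size_table,
    roc_analysis,
)
from .fcm import LesionMask, segment_lesion
from .projection import project
from .scoring import ScoreRecord, score_grid
from .volumes import DCEStudy, subtract

log = logging.getLogger("bpequant")


@dataclass
class PipelineConfig:
    """All stage parameters of the scoring pipeline, with reference defaults."""

    # lesion segmentation (fuzzy c-means); c=3 separates fat / enhancing
    # parenchyma / lesion intensity classes within the ROI
    fcm_c: int = 3
    fcm_m: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    fcm_membership_threshold: float = 0.5
    # electronic lesion removal
    ring_width: int = 1
    # breast segmentation
    unet_threshold: float = 0.25
    split_mode: str = "bbox"  # {bbox, centroid}
    segmenter: str = "unet"  # {unet, fallback}
    # scoring
    window_percentile: float = 100.0
    # evaluation
    roc_method: str = "empirical"
    n_comparisons: int = 13
    seed: int = 0


@dataclass
class ExamResult:
    exam_id: str
    records: list[ScoreRecord]
    lesion: LesionMask | None
    masks: object
    error: str | None = None


def records_to_dataframe(records: list[ScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def run_exam(
    study: DCEStudy,
    config: PipelineConfig,
    roi: tuple[slice, slice, slice] | None = None,
    segmenter: BreastSegmenter | None = None,
) -> ExamResult:
    """Run the full pipeline on one exam.

    ``roi`` is the manifest-supplied box around the diagnosed lesion (no
    ROI: removal is skipped and before == after).  ``segmenter`` is the
    trained breast segmenter; when absent, or when the config selects it,
    the non-learned fallback is used.  The affected side comes from the
    study; if unknown and a lesion was segmented, the side containing the
    lesion centroid is used.
    """
    sub2 = subtract(study, 2)

    lesion = None
    if roi is not None:
        lesion = segment_lesion(
            sub2, roi,
            c=config.fcm_c, m=config.fcm_m,
            membership_threshold=config.fcm_membership_threshold,
            tol=config.fcm_tol, max_iter=config.fcm_max_iter, seed=config.seed,
        )

    mip2 = project(sub2, "MIP")
    if config.segmenter == "unet" and segmenter is not None:
        prob = predict_probability(segmenter, mip2)
    else:
        if config.segmenter == "unet":
            warnings.warn("no trained segmenter supplied; using fallback segmenter")
        prob = fallback_segmenter(mip2)
    both = postprocess_mask(prob, threshold=config.unet_threshold)

    affected_side = study.affected_side
    if affected_side == "unknown" and lesion is not None and lesion.mask_3d.any():
        centroid_col = float(np.mean(np.nonzero(lesion.mask_3d)[2]))
        cols = np.nonzero(both.any(axis=0))[0]
        c0, c1 = int(cols.min()), int(cols.max())
        split = c0 + (c1 - c0 + 1) // 2
        affected_side = "left" if centroid_col < split else "right"
    masks = split_breasts(both, affected_side, mode=config.split_mode)

    records = score_grid(
        study, masks,
        lesion=lesion,
        ring_width=config.ring_width,
        window_percentile=config.window_percentile,
    )
    return ExamResult(exam_id=study.exam_id, records=records, lesion=lesion, masks=masks)


def run_cohort(
    exams: list[dict],
    config: PipelineConfig,
    segmenter: BreastSegmenter | None = None,
) -> dict:
    """Run the pipeline over a cohort and evaluate the scores.

    ``exams`` is a list of dicts with keys ``study`` (DCEStudy) and
    optionally ``roi``.  One failing exam is recorded and skipped; the run
    continues.  Returns a dict with the tidy score table, lesion sizes,
    the per-variant evaluation table, the ratio-vs-size tables and the
    list of failed exams.
    """
    all_records: list[ScoreRecord] = []
    sizes: dict[str, float] = {}
    failures: list[dict] = []
    for exam in exams:
        study: DCEStudy = exam["study"]
        try:
            res = run_exam(study, config, roi=exam.get("roi"), segmenter=segmenter)
            all_records.extend(res.records)
            if res.lesion is not None:
                sizes[study.exam_id] = res.lesion.size_mm
        except Exception as err:  # failure isolation: log and continue
            log.warning("exam %s failed: %s", study.exam_id, err)
            failures.append({"exam_id": study.exam_id, "error": str(err)})
    scores = records_to_dataframe(all_records)

    out = {"scores": scores, "lesion_sizes": sizes, "failures": failures,
           "evaluation": pd.DataFrame(), "ratio_per_exam": pd.DataFrame(),
           "ratio_aggregate": pd.DataFrame()}
    if scores.empty:
        return out

    ratings = scores.drop_duplicates("exam_id").set_index("exam_id").rating
    if ratings.nunique() >= 2:
        out["evaluation"] = evaluate_scores(scores, config)
    else:
        log.warning("fewer than 2 rating classes present; evaluation skipped")
    if sizes:
        per_exam, agg = ratio_vs_size_table(scores, sizes)
        out["ratio_per_exam"] = per_exam
        out["ratio_aggregate"] = agg
    return out


def evaluate_scores(scores: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Tau-b and both-task ROC per image variant present in the score table."""
    rows = []
    keys = ["region", "projection_type", "time_point", "rescale_mode", "lesion_removed"]
    for variant, grp in scores.groupby(keys, sort=True):
        grp = grp.dropna(subset=["rating"])
        if grp.rating.nunique() < 2:
            continue
        row = dict(zip(keys, variant))
        row["n"] = len(grp)
        try:
            corr = kendall_tau_b(grp.rating.to_numpy(), grp.score.to_numpy())
            row.update(tau_b=corr.tau_b, tau_p=corr.p_value)
        except ValueError:
            row.update(tau_b=np.nan, tau_p=np.nan)
        for task in TASKS:
            try:
                labels, keep = dichotomize(grp.rating.to_numpy(), task)
                roc = roc_analysis(
                    grp.score.to_numpy()[keep], labels,
                    method=config.roc_method, n_comparisons=config.n_comparisons,
                )
                row[f"auc_{task}"] = roc.auc
                row[f"se_{task}"] = roc.se
                row[f"p_{task}"] = roc.p_vs_chance
                row[f"p_corrected_{task}"] = roc.p_corrected
            except ValueError:
                row[f"auc_{task}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
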