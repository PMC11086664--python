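"""Statistical evaluation of computer BPE scores against radiologist ratings.

Implements Kendall's tau-b rank correlation with a tie-corrected normal
approximation for significance, empirical ROC analysis (Mann-Whitney AUC
with the 0.5 tie convention, DeLong standard error, z-test against chance
with Bonferroni correction), an optional conventional binormal
maximum-likelihood ROC fit on rank-binned data, and the after/before
score-ratio versus lesion-size summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .volumes import BPE_LEVEL_CODE, BPE_LEVELS

TASKS = ("minimal_vs_marked", "low_vs_high")


@dataclass
class CorrelationResult:
    tau_b: float
    z_statistic: float
    p_value: float
    n: int


@dataclass
class ROCResult:
    auc: float
    se: float
    p_vs_chance: float
    p_corrected: float
    n_pos: int
    n_neg: int
    curve_points: np.ndarray  # (k, 2) array of (FPR, TPR)
    method: str  # {empirical, binormal}
    z_statistic: float = float("nan")
    binormal_params: tuple[float, float] | None = None  # (a, b)


def kendall_tau_b(ratings, scores) -> CorrelationResult:
    """Kendall's tau-b between ordinal ratings and continuous scores.

    tau_b = (P - Q) / sqrt((P + Q + T_x)(P + Q + T_y)) with concordant P,
    discordant Q and tie terms T; significance uses the normal approximation
    of S = P - Q under the null, with the tie-corrected variance.  Ratings
    may be level names or numeric codes.
    """
    x = np.asarray([BPE_LEVEL_CODE.get(r, r) for r in ratings], dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("ratings and scores must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("tau-b undefined: one of the variables is constant")

    tau = float(stats.kendalltau(x, y, variant="b").statistic)

    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    s = float((dx[iu] * dy[iu]).sum())  # P - Q

    def tie_sums(v: np.ndarray):
        _, counts = np.unique(v, return_counts=True)
        t = counts[counts > 1].astype(float)
        return (
            (t * (t - 1) * (2 * t + 5)).sum(),
            (t * (t - 1) * (t - 2)).sum(),
            (t * (t - 1)).sum(),
        )

    vt, vt3, vt2 = tie_sums(x)
    vu, vu3, vu2 = tie_sums(y)
    var_s = (
        (n * (n - 1) * (2 * n + 5) - vt - vu) / 18.0
        + vt3 * vu3 / (9.0 * n * (n - 1) * (n - 2))
        + vt2 * vu2 / (2.0 * n * (n - 1))
    )
    z = s / np.sqrt(var_s) if var_s > 0 else float("nan")
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return CorrelationResult(tau_b=tau, z_statistic=float(z), p_value=p, n=n)


def dichotomize(ratings, task: str) -> tuple[np.ndarray, np.ndarray]:
    """Binary labels for one BPE classification task.

    ``minimal_vs_marked``: minimal negative, marked positive, mild and
    moderate exams dropped.  ``low_vs_high``: minimal+mild negative,
    moderate+marked positive, all exams kept.  Returns (labels, keep_index)
    where ``keep_index`` selects the retained exams.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    codes = np.asarray([BPE_LEVEL_CODE.get(r, r) for r in ratings], dtype=int)
    if task == "minimal_vs_marked":
        keep = np.flatnonzero((codes == 1) | (codes == 4))
        labels = (codes[keep] == 4).astype(int)
    else:
        keep = np.arange(codes.size)
        labels = (codes >= 3).astype(int)
    for cls, name in ((0, "negative"), (1, "positive")):
        if not (labels == cls).any():
            raise ValueError(f"task {task}: {name} class is empty")
    return labels, keep


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def _delong_se(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = 0.0
    if pos.size > 1:
        var += v10.var(ddof=1) / pos.size
    if neg.size > 1:
        var += v01.var(ddof=1) / neg.size
    return float(np.sqrt(var))


def _binormal_fit(scores: np.ndarray, labels: np.ndarray, n_bins: int = 10):
    """Conventional binormal MLE (Dorfman-Alf) on rank-binned scores.

    Negatives ~ N(0,1), positives ~ N(a/b, 1/b); category boundaries are
    free parameters.  Returns (a, b, auc, curve_points).
    """
    edges = np.unique(np.quantile(scores, np.linspace(0, 1, n_bins + 1)[1:-1]))
    cats = np.searchsorted(edges, scores, side="right")
    k = edges.size + 1
    neg_counts = np.bincount(cats[labels == 0], minlength=k)
    pos_counts = np.bincount(cats[labels == 1], minlength=k)

    def unpack(theta):
        a, logb = theta[0], theta[1]
        b = np.exp(logb)
        cuts = np.cumsum(np.concatenate([[theta[2]], np.exp(theta[3:])]))
        return a, b, cuts

    def nll(theta):
        a, b, cuts = unpack(theta)
        cn = np.concatenate([[0.0], stats.norm.cdf(cuts), [1.0]])
        cp = np.concatenate([[0.0], stats.norm.cdf(b * cuts - a), [1.0]])
        pn = np.clip(np.diff(cn), 1e-12, None)
        pp = np.clip(np.diff(cp), 1e-12, None)
        return -(neg_counts * np.log(pn)).sum() - (pos_counts * np.log(pp)).sum()

    # moment-based start
    mu0, sd0 = scores[labels == 0].mean(), scores[labels == 0].std() + 1e-9
    mu1, sd1 = scores[labels == 1].mean(), scores[labels == 1].std() + 1e-9
    z = (edges - mu0) / sd0 if edges.size else np.array([0.0])
    b0 = sd0 / sd1
    a0 = (mu1 - mu0) / sd1
    theta0 = np.concatenate([[a0, np.log(b0)], [z[0]], np.log(np.clip(np.diff(z), 1e-3, None))])
    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    a, b, _ = unpack(res.x)
    auc = float(stats.norm.cdf(a / np.sqrt(1.0 + b**2)))
    fpr = np.linspace(0, 1, 101)
    with np.errstate(divide="ignore"):
        tpr = stats.norm.cdf(a + b * stats.norm.ppf(fpr))
    tpr[0], tpr[-1] = 0.0, 1.0
    return a, b, auc, np.column_stack([fpr, tpr])


def roc_analysis(
    scores,
    labels,
    method: str = "empirical",
    n_comparisons: int = 1,
) -> ROCResult:
    """ROC analysis of scores against binary labels, tested against chance.

    Empirical method: Mann-Whitney AUC (ties 0.5), DeLong SE,
    z = (AUC - 0.5)/SE with a two-sided p, Bonferroni-corrected by
    ``n_comparisons``.  Binormal method: conventional binormal MLE on
    rank-binned data (SE and test still from the empirical estimator).
    """
    from sklearn.metrics import roc_curve

    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")

    if np.unique(s).size == 1:
        warnings.warn("degenerate single-valued scores: AUC 0.5 with infinite SE")
        curve = np.array([[0.0, 0.0], [1.0, 1.0]])
        return ROCResult(auc=0.5, se=float("inf"), p_vs_chance=1.0, p_corrected=1.0,
                         n_pos=n_pos, n_neg=n_neg, curve_points=curve,
                         method=method, z_statistic=0.0)

    auc = _mann_whitney_auc(s, y)
    se = _delong_se(s, y)
    z = (auc - 0.5) / se if se > 0 else float("inf") * np.sign(auc - 0.5)
    p = float(2.0 * stats.norm.sf(abs(z)))
    fpr, tpr, _ = roc_curve(y, s)
    curve = np.column_stack([fpr, tpr])

    result = ROCResult(
        auc=auc, se=se, p_vs_chance=p,
        p_corrected=min(1.0, p * n_comparisons),
        n_pos=n_pos, n_neg=n_neg, curve_points=curve,
        method="empirical", z_statistic=float(z),
    )
    if method == "binormal":
        a, b, auc_b, curve_b = _binormal_fit(s, y)
        result.method = "binormal"
        result.auc = auc_b
        result.curve_points = curve_b
        result.binormal_params = (float(a), float(b))
    elif method != "empirical":
        raise ValueError(f"unknown ROC method {method!r}")
    return result


def ratio_vs_size_table(
    records: pd.DataFrame,
    sizes: dict[str, float],
    region: str = "affected",
    projection_type: str = "MIP",
    time_point: int = 2,
    rescale_mode: str = "rescaled",
    size_bin_edges: tuple[float, ...] = (0.0, 10.0, 20.0, 35.0, 70.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """After/before score ratios per exam, with size-bin and level aggregates.

    ``records`` is a tidy score table (one row per ScoreRecord); ``sizes``
    maps exam id to lesion size in mm.  Exams missing a before/after pair
    are skipped with a warning.  Returns (per-exam table, aggregate table);
    the aggregate table holds the mean ratio by rating level and size bin.
    """
    sel = records[
        (records.region == region)
        & (records.projection_type == projection_type)
        & (records.time_point == time_point)
        & (records.rescale_mode == rescale_mode)
    ]
    rows = []
    for exam_id, grp in sel.groupby("exam_id", sort=True):
        before = grp[~grp.lesion_removed]
        after = grp[grp.lesion_removed]
        if len(before) != 1 or len(after) != 1:
            warnings.warn(f"exam {exam_id}: missing before/after score pair; skipped")
            continue
        b = float(before.score.iloc[0])
        a = float(after.score.iloc[0])
        if b <= 0:
            warnings.warn(f"exam {exam_id}: zero score before removal; skipped")
            continue
        rows.append({
            "exam_id": exam_id,
            "rating": before.rating.iloc[0],
            "size_mm": float(sizes.get(exam_id, np.nan)),
            "score_before": b,
            "score_after": a,
            "ratio": a / b,
        })
    per_exam = pd.DataFrame(rows)
    if per_exam.empty:
        return per_exam, pd.DataFrame()
    per_exam["size_bin"] = pd.cut(per_exam.size_mm, bins=list(size_bin_edges))
    agg = (
        per_exam.groupby(["rating", "size_bin"], observed=True)["ratio"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_ratio", "count": "n"})
    )
    return per_exam, agg


def plot_ratio_vs_size(per_exam: pd.DataFrame, path=None):
    """Scatter of after/before ratio versus lesion size, coloured by rating."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for level in BPE_LEVELS:
        sub = per_exam[per_exam.rating == level]
        if len(sub):
            ax.scatter(sub.size_mm, sub.ratio, s=18, label=level, alpha=0.75)
    ax.axhline(1.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("lesion size (mm)")
    ax.set_ylabel("BPE score ratio (after / before removal)")
    ax.legend(title="BPE level", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
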