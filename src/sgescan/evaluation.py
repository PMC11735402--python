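"""Clinical calibration of fitness scores and related evaluation tools.

Covers truth-set confusion metrics, PR/ROC curves, the OddsPath
functional-evidence calculus with ACMG/AMP strength labels, the Z'
assay-quality factor, rescaling of external screens onto the RFS scale
with quadrant comparison, trinucleotide mutational-signature
probabilities, and Spearman correlation of scores against covariates.

OddsPath converts a functional classifier's performance on clinical
truth sets into odds of pathogenicity: with P1 the prior pathogenic
fraction among all controls and P2 the pathogenic fraction among
variants classified abnormal (PS3) or normal (BS3),

    OddsPath = [P2 * (1 - P1)] / [(1 - P2) * P1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import precision_recall_curve, roc_curve

from sgescan.library_design import LibraryTable
from sgescan.scoring import rfs_transform
from sgescan.seqmodel import reverse_complement

__all__ = [
    "ConfusionMetrics",
    "OddsPathResult",
    "classify_function",
    "confusion_metrics",
    "correlate",
    "oddspath",
    "pr_roc",
    "quadrant_labels",
    "rescale_external_screen",
    "sbs_mean_probability",
    "z_prime",
]

#: published ACMG/AMP functional-evidence OddsPath thresholds
PS3_STRENGTH_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (350.0, "very strong"),
    (18.7, "strong"),
    (4.3, "moderate"),
    (2.1, "supporting"),
)
BS3_STRENGTH_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.0029, "very strong"),
    (0.053, "strong"),
    (0.23, "moderate"),
    (0.48, "supporting"),
)


def classify_function(rfs: pd.Series, threshold: float = 0.0) -> pd.Series:
    """Label variants ``abnormal`` iff RFS is strictly above the threshold."""
    return pd.Series(
        np.where(rfs > threshold, "abnormal", "normal"), index=rfs.index, name="function"
    )


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fn: int
    fp: int
    tn: int
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]


def confusion_metrics(truth: pd.Series, predicted: pd.Series) -> ConfusionMetrics:
    """Confusion table and precision/recall/F1 for binary truth labels.

    ``truth`` holds ``pathogenic``/``benign``; ``predicted`` holds
    ``abnormal``/``normal``.  Metrics with a zero denominator are
    reported as None rather than 0.
    """
    truth, predicted = truth.align(predicted, join="inner")
    if truth.empty:
        raise ValueError("no overlapping variants between truth and prediction")
    is_path = truth == "pathogenic"
    is_abn = predicted == "abnormal"
    tp = int((is_path & is_abn).sum())
    fn = int((is_path & ~is_abn).sum())
    fp = int((~is_path & is_abn).sum())
    tn = int((~is_path & ~is_abn).sum())
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision is not None and recall is not None and (precision + recall) > 0
        else None
    )
    return ConfusionMetrics(tp, fn, fp, tn, precision, recall, f1)


def pr_roc(truth: pd.Series, scores: pd.Series) -> dict:
    """Threshold-sweep precision-recall and ROC curves with trapezoidal AUCs.

    Equal scores are grouped into a single threshold step, which avoids
    optimistic interpolation through tied blocks.
    """
    truth, scores = truth.align(scores.dropna(), join="inner")
    y = (truth == "pathogenic").astype(int).values
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both truth classes must be present")
    s = scores.values.astype(float)
    precision, recall, pr_thresh = precision_recall_curve(y, s)
    fpr, tpr, roc_thresh = roc_curve(y, s)
    # precision_recall_curve emits points with non-increasing recall down
    # to the terminal (recall 0, precision 1) point; integrating in the
    # reversed (threshold-sweep) order keeps tied-recall blocks as
    # zero-width steps instead of reordering them
    pr_auc = float(np.trapezoid(np.asarray(precision)[::-1], np.asarray(recall)[::-1]))
    roc_auc = float(np.trapezoid(tpr, fpr))
    return {
        "precision": precision,
        "recall": recall,
        "fpr": fpr,
        "tpr": tpr,
        "pr_auc": pr_auc,
        "roc_auc": roc_auc,
    }


@dataclass(frozen=True)
class OddsPathResult:
    ps3: float
    bs3: float
    ps3_strength: str
    bs3_strength: str


def _odds(p2: float, p1: float) -> float:
    if p2 >= 1.0:
        return math.inf
    if p2 <= 0.0:
        return 0.0
    return (p2 * (1.0 - p1)) / ((1.0 - p2) * p1)


def _ps3_label(value: float) -> str:
    for cut, label in PS3_STRENGTH_THRESHOLDS:
        if value >= cut:
            return label
    return "indeterminate"


def _bs3_label(value: float) -> str:
    for cut, label in BS3_STRENGTH_THRESHOLDS:
        if value <= cut:
            return label
    return "indeterminate"


def oddspath(tp: int, fn: int, fp: int, tn: int, correction: bool = False) -> OddsPathResult:
    """OddsPath for pathogenic (PS3) and benign (BS3) evidence.

    P1 is the pathogenic fraction of all controls; for PS3, P2 is the
    pathogenic fraction among variants classified abnormal; for BS3, the
    pathogenic fraction among variants classified normal.  A zero
    misclassification cell yields an infinite (or zero) value unless the
    0.5 continuity ``correction`` is applied to every cell.
    """
    total = tp + fn + fp + tn
    if fp + tn <= 0 or total <= 0:
        raise ValueError("truth set must contain benign controls")
    if correction:
        tp, fn, fp, tn = (x + 0.5 for x in (tp, fn, fp, tn))
        total = tp + fn + fp + tn
    p1 = (tp + fn) / total
    p2_ps3 = tp / (tp + fp) if tp + fp else float("nan")
    p2_bs3 = fn / (fn + tn) if fn + tn else float("nan")
    ps3 = _odds(p2_ps3, p1)
    bs3 = _odds(p2_bs3, p1)
    return OddsPathResult(ps3, bs3, _ps3_label(ps3), _bs3_label(bs3))


def z_prime(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Z' = 1 - 3 (sigma_pos + sigma_neg) / |mu_pos - mu_neg| (sample SDs)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("both control sets need at least two values")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        raise ValueError("control means coincide; Z' undefined")
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep


def quadrant_labels(x: pd.Series, y: pd.Series) -> pd.Series:
    """Quadrant per variant with the split at (0, 0), strict > 0 positive.

    x is this screen's RFS, y the external screen's rescaled score:
    lower-right = LOF here but WT-like externally.
    """
    x, y = x.align(y, join="inner")
    labels = np.where(
        x > 0,
        np.where(y > 0, "upper-right", "lower-right"),
        np.where(y > 0, "upper-left", "lower-left"),
    )
    return pd.Series(labels, index=x.index, name="quadrant")


def rescale_external_screen(
    scores: pd.Series,
    nonsense_ids: Iterable[str],
    synonymous_ids: Iterable[str],
    reference_rfs: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Rescale an external screen's scores onto the RFS scale.

    The nonsense-control median maps to +1 and the synonymous median to
    -1 exactly as for the primary screen.  With ``reference_rfs`` given,
    quadrant labels are attached (x = reference RFS, y = rescaled
    external RFS).
    """
    rescaled = rfs_transform(scores, nonsense_ids, synonymous_ids)
    out = pd.DataFrame({"external_rfs": rescaled})
    if reference_rfs is not None:
        out = out.join(pd.DataFrame({"reference_rfs": reference_rfs}), how="inner")
        out["quadrant"] = quadrant_labels(out["reference_rfs"], out["external_rfs"])
    return out


# ---------------------------------------------------------------------
# mutational-signature probability

_PYRIMIDINES = frozenset("CT")


def trinucleotide_channel(ref: str, alt: str, left: str, right: str) -> str:
    """Map an SNV with flanking context to its pyrimidine-strand channel."""
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValueError("need a single-nucleotide substitution")
    if ref not in _PYRIMIDINES:
        ref, alt = reverse_complement(ref), reverse_complement(alt)
        left, right = reverse_complement(right), reverse_complement(left)
    return f"{left}[{ref}>{alt}]{right}"


def sbs_mean_probability(
    library: LibraryTable,
    signatures: pd.DataFrame,
    weights: pd.Series,
) -> pd.Series:
    """Per-variant mutational probability under a prevalence-weighted mean
    single-base-substitution signature.

    ``signatures`` is indexed by the 96 trinucleotide channels (e.g.
    ``A[C>T]G``) with one column per signature; ``weights`` holds the
    per-signature prevalence.  Only single-nucleotide substitutions with
    both flanking bases inside the variable region receive a value;
    other variants are NaN (not applicable).
    """
    w = weights.reindex(signatures.columns).fillna(0.0)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    sbs_mean = signatures.mul(w, axis=1).sum(axis=1) / w.sum()

    probs = pd.Series(np.nan, index=[r.variant_id for r in library.records])
    for rec in library.records:
        e = rec.edit
        if e.kind != "substitution" or len(e.ref) != 1:
            continue
        wt = library.wt_sequences[rec.region]
        if e.pos == 0 or e.pos >= len(wt) - 1:
            continue  # context unavailable at the region edge
        channel = trinucleotide_channel(e.ref, e.alt, wt[e.pos - 1], wt[e.pos + 1])
        if channel in sbs_mean.index:
            probs.loc[rec.variant_id] = float(sbs_mean.loc[channel])
    return probs.rename("sbs_mean_probability")


def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """Spearman rank correlation with a two-tailed t-approximation p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least three paired finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    if method != "spearman":
        raise ValueError(f"unsupported method {method!r}")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
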