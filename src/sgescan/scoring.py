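"""Enrichment scores, RFS normalization and the synonymous-null z-test.

The enrichment score (ES) of a variant is the log2 fold change of its
relative abundance under treatment versus control.  Because the ES scale
depends on the library composition, it is rescaled per exon into a
relative fitness score (RFS) by the affine map

    RFS(ES) = (ES - med_non) / (med_non - med_syn) * 2 + 1

which anchors the median of the nonsense controls at +1 and the median
of the synonymous controls at -1.  Per-variant significance against the
synonymous null uses a log-ratio count score with a Poisson-derived
standard error (the Enrich2 "log ratios" estimator with pseudocount
0.5), a one-sided z-test against the inverse-variance weighted mean of
the synonymous scores, and Benjamini-Hochberg correction.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from sgescan.counting import CountMatrix

__all__ = [
    "NormalizationError",
    "aggregate_replicates",
    "count_score_with_se",
    "enrichment_scores",
    "rfs_transform",
    "score_screen",
    "syn_null_ztest",
]

_LN2 = np.log(2.0)


class NormalizationError(ValueError):
    """Control medians coincide; the RFS map is undefined."""


def enrichment_scores(
    treated: pd.Series,
    control: pd.Series,
    pseudocount: float = 0.0,
    counts: bool = False,
) -> pd.Series:
    """ES = log2(f_treated / f_control) over a shared variant universe.

    With ``counts=True`` the inputs are raw counts and frequencies are
    estimated as (c + pseudocount) / (N + pseudocount); otherwise the
    inputs are relative abundances and a zero control frequency yields a
    missing score (NaN) unless a pseudocount shifts both frequencies.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    treated, control = treated.align(control, join="inner")
    if counts:
        ft = (treated + pseudocount) / (treated.sum() + pseudocount)
        fc = (control + pseudocount) / (control.sum() + pseudocount)
    else:
        ft = treated + pseudocount
        fc = control + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        es = np.log2(ft.astype(float)) - np.log2(fc.astype(float))
    es[np.asarray(fc) == 0] = np.nan
    return pd.Series(es, index=treated.index, name="ES")


def rfs_transform(
    es: pd.Series,
    nonsense_ids: Iterable[str],
    synonymous_ids: Iterable[str],
) -> pd.Series:
    """Affine control-anchored normalization of an ES vector."""
    non = es.reindex(pd.Index(nonsense_ids).intersection(es.index)).dropna()
    syn = es.reindex(pd.Index(synonymous_ids).intersection(es.index)).dropna()
    if non.empty or syn.empty:
        raise NormalizationError("both control sets must be non-empty")
    med_non = float(non.median())
    med_syn = float(syn.median())
    if med_non == med_syn:
        raise NormalizationError("nonsense and synonymous medians coincide")
    return (es - med_non) / (med_non - med_syn) * 2.0 + 1.0


def aggregate_replicates(rfs: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Median across replicate columns plus median absolute deviation."""
    if rfs.shape[1] < 1:
        raise ValueError("at least one replicate required")
    med = rfs.median(axis=1)
    mad = (rfs.sub(med, axis=0)).abs().median(axis=1)
    return med.rename("RFS_median"), mad.rename("RFS_mad")


def count_score_with_se(c0, N0, c1, N1, pseudocount: float = 0.5):
    """Log-ratio count score and its standard error (log2 units).

    score = log2((c1+p)/N1) - log2((c0+p)/N0)
    SE    = sqrt(1/(c1+p) + 1/(c0+p)) / ln 2
    """
    if np.any(np.asarray(N0) <= 0) or np.any(np.asarray(N1) <= 0):
        raise ValueError("totals must be positive")
    c0 = np.asarray(c0, dtype=float) + pseudocount
    c1 = np.asarray(c1, dtype=float) + pseudocount
    score = np.log2(c1 / np.asarray(N1, dtype=float)) - np.log2(c0 / np.asarray(N0, dtype=float))
    se = np.sqrt(1.0 / c1 + 1.0 / c0) / _LN2
    return score, se


def syn_null_ztest(
    scores: pd.Series,
    ses: pd.Series,
    synonymous_ids: Iterable[str],
) -> pd.DataFrame:
    """One-sided z-test of each score against the synonymous null.

    The null mean is the inverse-variance weighted mean of the
    synonymous scores; its squared standard error is 1 / sum(1/SE_i^2).
    z = (s - mu_syn) / sqrt(SE^2 + SE_mu^2), upper-tail p, BH-adjusted q.
    """
    scores, ses = scores.align(ses, join="inner")
    if (ses <= 0).any():
        raise ValueError("all standard errors must be positive")
    syn_idx = pd.Index(synonymous_ids).intersection(scores.index)
    syn_scores = scores.loc[syn_idx].dropna()
    syn_ses = ses.loc[syn_scores.index]
    if syn_scores.empty:
        raise ValueError("synonymous control set is empty")
    w = 1.0 / syn_ses**2
    mu = float((w * syn_scores).sum() / w.sum())
    se_mu2 = 1.0 / float(w.sum())
    z = (scores - mu) / np.sqrt(ses**2 + se_mu2)
    p = pd.Series(sps.norm.sf(z), index=scores.index)
    q = pd.Series(np.nan, index=scores.index)
    ok = p.notna()
    if ok.any():
        q.loc[ok] = multipletests(p[ok].values, method="fdr_bh")[1]
    return pd.DataFrame({"z": z, "p": p, "q": q})


def score_screen(
    counts: CountMatrix,
    annotation: pd.DataFrame,
    treated: str = "treated",
    control: str = "control",
    pseudocount: float = 0.5,
    min_control_count: int = 0,
) -> pd.DataFrame:
    """Full per-variant score table for one screen.

    ``annotation`` is the library table frame (index variant_id, columns
    at least ``region`` and ``coding_class``).  Per replicate, ES values
    are computed from raw counts with the given pseudocount and rescaled
    to RFS per region (exon sub-library); RFS_median aggregates the
    replicates.  In parallel a combined log-ratio count score with
    standard error (inverse-variance pooling over replicates) feeds the
    one-sided synonymous-null z-test on the RFS scale.

    Variants whose control count falls below ``min_control_count`` in
    any replicate are flagged (column ``low_control_count``), not
    dropped.
    """
    ann = annotation.loc[annotation.index.intersection(counts.counts.index)]
    out = pd.DataFrame(index=ann.index)
    out["region"] = ann["region"]
    out["coding_class"] = ann["coding_class"]

    pairs = list(counts.replicate_pairs(treated, control))
    if not pairs:
        raise ValueError(f"no replicate pairs for conditions {treated!r}/{control!r}")

    nonsense = ann.index[ann["coding_class"] == "nonsense"]
    synonymous = ann.index[ann["coding_class"] == "synonymous"]

    es_cols, rfs_cols = [], []
    scores_reps, ses_reps = [], []
    low = pd.Series(False, index=ann.index)
    for rep, ccol, tcol in pairs:
        c = counts.counts.loc[ann.index, ccol]
        t = counts.counts.loc[ann.index, tcol]
        low |= c < min_control_count
        es = enrichment_scores(t, c, pseudocount=pseudocount, counts=True)
        out[f"ES_rep{rep}"] = es
        es_cols.append(f"ES_rep{rep}")
        rfs = pd.Series(np.nan, index=ann.index)
        for region, members in ann.groupby("region").groups.items():
            rfs.loc[members] = rfs_transform(
                es.loc[members],
                nonsense.intersection(members),
                synonymous.intersection(members),
            )
        out[f"RFS_rep{rep}"] = rfs
        rfs_cols.append(f"RFS_rep{rep}")
        s, se = count_score_with_se(c.values, c.sum(), t.values, t.sum(), pseudocount)
        scores_reps.append(pd.Series(s, index=ann.index))
        ses_reps.append(pd.Series(se, index=ann.index))

    med, mad = aggregate_replicates(out[rfs_cols])
    out["RFS_median"] = med
    out["RFS_mad"] = mad

    # inverse-variance pooled count score across replicates
    w = sum(1.0 / se**2 for se in ses_reps)
    score = sum(s / se**2 for s, se in zip(scores_reps, ses_reps)) / w
    se = np.sqrt(1.0 / w)
    out["score"] = score
    out["SE"] = se

    # rescale the pooled score (and its SE) to the RFS scale per region
    tscore = pd.Series(np.nan, index=ann.index)
    tse = pd.Series(np.nan, index=ann.index)
    for region, members in ann.groupby("region").groups.items():
        sub = score.loc[members]
        med_non = sub.loc[nonsense.intersection(members)].median()
        med_syn = sub.loc[synonymous.intersection(members)].median()
        if med_non == med_syn:
            raise NormalizationError(f"degenerate control medians in region {region}")
        scale = 2.0 / (med_non - med_syn)
        tscore.loc[members] = (sub - med_non) * scale + 1.0
        tse.loc[members] = se.loc[members] * abs(scale)
    out["transformed_score"] = tscore
    out["transformed_SE"] = tse

    zpq = syn_null_ztest(tscore, tse, synonymous)
    out = out.join(zpq)
    out["low_control_count"] = low
    return out
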