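"""Nonsense-mediated decay detection from paired mRNA/DNA counts.

A variant transcribed but degraded by NMD is depleted in the mRNA pool
relative to its genomic-DNA representation.  Per variant, relative
abundances are computed for every replicate of each material, aggregated
across replicates by the median, and compared as

    log2FC = log2(median mRNA abundance) - log2(median DNA abundance).

Variants with log2FC < -2 are classified NMD-positive; variants with a
mean cDNA read count below 5 carry too little evidence and are marked
not evaluable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["classify_nmd", "nmd_log2fc"]


def classify_nmd(log2fc, threshold: float = -2.0):
    """NMD-positive iff log2FC is strictly below the threshold."""
    arr = np.asarray(log2fc, dtype=float)
    result = arr < threshold
    if np.ndim(log2fc) == 0:
        return bool(result)
    if isinstance(log2fc, pd.Series):
        return pd.Series(result, index=log2fc.index)
    return result


def _median_abundance(counts: pd.DataFrame, pseudocount: float) -> pd.Series:
    ab = (counts + pseudocount).div(counts.sum(axis=0) + pseudocount, axis=1)
    return ab.median(axis=1)


def nmd_log2fc(
    mrna: pd.DataFrame,
    dna: pd.DataFrame,
    min_mean_cdna_count: float = 5.0,
    threshold: float = -2.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Build the per-variant NMD table from replicate count frames.

    ``mrna`` and ``dna`` are variants x replicates count tables sharing
    a variant index.  Returns a frame with median abundances, log2FC,
    the mean cDNA count, an ``evaluable`` flag and the ``nmd_positive``
    call (pandas NA where not evaluable).
    """
    common = mrna.index.intersection(dna.index)
    if common.empty:
        raise ValueError("mRNA and DNA tables share no variants")
    mrna = mrna.loc[common]
    dna = dna.loc[common]

    mrna_ab = _median_abundance(mrna, pseudocount)
    dna_ab = _median_abundance(dna, pseudocount)
    log2fc = np.log2(mrna_ab) - np.log2(dna_ab)
    mean_cdna = mrna.mean(axis=1)
    evaluable = mean_cdna >= min_mean_cdna_count

    call = pd.Series(pd.NA, index=common, dtype="boolean")
    call[evaluable] = classify_nmd(log2fc[evaluable], threshold)
    return pd.DataFrame(
        {
            "dna_abundance": dna_ab,
            "mrna_abundance": mrna_ab,
            "log2fc_mrna_dna": log2fc,
            "mean_cdna_count": mean_cdna,
            "evaluable": evaluable,
            "nmd_positive": call,
        }
    )
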