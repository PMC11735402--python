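"""Exact-match variant counting from merged amplicon reads.

Reads are trimmed of their constant flanks and the interior is looked up
against the library's full variable-region sequences.  Because the
library guarantees a minimum pairwise Hamming distance of 1, exact
matching assigns each read to at most one variant; reads equal to the
wild-type region or matching nothing are tallied separately and
discarded.  No mismatch rescue is attempted: with adjacent variants one
substitution apart, error-tolerant matching would misassign reads.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from sgescan.library_design import LibraryTable

__all__ = [
    "CountMatrix",
    "DegenerateSampleError",
    "ReadStats",
    "count_reads",
    "read_fastq",
    "relative_abundance",
    "trim_to_variable_region",
]


class DegenerateSampleError(ValueError):
    """A sample with no matched reads cannot be normalized."""


@dataclass
class ReadStats:
    reads_in: int = 0
    flank_fail: int = 0
    wt_discarded: int = 0
    unmatched: int = 0
    matched: int = 0

    def consistent(self) -> bool:
        return self.reads_in == self.flank_fail + self.wt_discarded + self.unmatched + self.matched


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_to_variable_region(
    read: str,
    flank5: str,
    flank3: str,
    max_flank_mismatch: int = 0,
) -> tuple[Optional[str], Optional[str]]:
    """Strip constant flanks anchored at the read ends.

    Returns ``(interior, None)`` on success or ``(None, reason)`` when
    the read is too short or either flank exceeds the Hamming mismatch
    tolerance.
    """
    if not flank5 or not flank3:
        raise ValueError("flanks must be non-empty")
    if len(read) < len(flank5) + len(flank3):
        return None, "flank_fail"
    head = read[: len(flank5)]
    tail = read[len(read) - len(flank3) :]
    if _hamming(head, flank5) > max_flank_mismatch or _hamming(tail, flank3) > max_flank_mismatch:
        return None, "flank_fail"
    return read[len(flank5) : len(read) - len(flank3)], None


def count_reads(
    reads: Iterable[str],
    library: LibraryTable,
    region: int,
    flanks: Optional[tuple[str, str]] = None,
    max_flank_mismatch: int = 0,
) -> tuple[pd.Series, ReadStats]:
    """Count exact matches of reads against one region's library.

    With ``flanks`` given, each read is first trimmed with
    :func:`trim_to_variable_region`; otherwise reads are assumed already
    trimmed to the variable region.
    """
    index = library.sequence_index(region)
    wt = library.wt_sequences[region]
    ids = [library.records[i].variant_id for i in range(len(library.records))
           if library.records[i].region == region]
    counts = dict.fromkeys(ids, 0)
    stats = ReadStats()
    for read in reads:
        stats.reads_in += 1
        if flanks is not None:
            interior, reason = trim_to_variable_region(
                read, flanks[0], flanks[1], max_flank_mismatch
            )
            if interior is None:
                stats.flank_fail += 1
                continue
            read = interior
        if read == wt:
            stats.wt_discarded += 1
        elif read in index:
            counts[index[read]] += 1
            stats.matched += 1
        else:
            stats.unmatched += 1
    return pd.Series(counts, name="count", dtype=int), stats


def relative_abundance(counts: pd.Series) -> pd.Series:
    """Counts divided by the total number of matched reads."""
    total = counts.sum()
    if total <= 0:
        raise DegenerateSampleError("no matched reads in sample")
    values = counts / total
    return values


@dataclass
class CountMatrix:
    """Variants x samples integer counts with sample metadata.

    ``samples`` is indexed by sample name with columns ``condition``
    (control/treated/...), ``replicate`` (int) and ``material``
    (DNA/mRNA).  ``stats`` holds per-sample read accounting.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def columns_for(self, condition: Optional[str] = None, material: Optional[str] = None) -> list[str]:
        meta = self.samples
        mask = pd.Series(True, index=meta.index)
        if condition is not None:
            mask &= meta["condition"] == condition
        if material is not None:
            mask &= meta["material"] == material
        return [c for c in self.counts.columns if c in meta.index[mask]]

    def replicate_pairs(self, treated: str, control: str, material: str = "DNA"):
        """Yield ``(replicate, control_column, treated_column)`` triples."""
        meta = self.samples
        for rep in sorted(meta["replicate"].unique()):
            sel_c = meta[
                (meta["condition"] == control)
                & (meta["replicate"] == rep)
                & (meta["material"] == material)
            ]
            sel_t = meta[
                (meta["condition"] == treated)
                & (meta["replicate"] == rep)
                & (meta["material"] == material)
            ]
            if len(sel_c) == 1 and len(sel_t) == 1:
                yield int(rep), sel_c.index[0], sel_t.index[0]

    def to_tsv(self, counts_path: str | Path, samples_path: Optional[str | Path] = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="variant_id")
        if samples_path is not None:
            self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="variant_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
        return cls(counts=counts, samples=samples)


def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield sequences from a (optionally gzipped) FASTQ file.

    Qualities are ignored: matching is exact and error correction is
    expected upstream in the paired-end merge.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ record near {header!r}")
            yield seq
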