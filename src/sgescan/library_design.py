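"""Exhaustive saturation-mutagenesis library design.

For each variable region (exon plus intronic flanks) the library is the
union of four enumerations:

* all single-nucleotide substitutions (3L edits for an L-nt region);
* multi-nucleotide codon substitutions completing, for every complete
  codon, the set of 19 missense targets plus STOP (and, where possible,
  one synonymous codon), each chosen as the codon with minimal Hamming
  distance to the reference;
* all single-base insertions (4L);
* all deletions of 1-3 nt (3L - 3 for L >= 3).

Records are deduplicated by their resulting full-region sequence, so the
minimum pairwise Hamming distance between equal-length distinct library
members is 1 -- the property that makes exact-match read counting
unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional

import pandas as pd

from sgescan.seqmodel import (
    CODON_TO_AA,
    CODONS_BY_AA,
    Consequence,
    Edit,
    TranscriptModel,
    annotate_edit,
    apply_edit,
    reverse_complement,
    translate,
)

__all__ = [
    "DesignConfig",
    "LibraryTable",
    "UnsilenceableMotifError",
    "VariantRecord",
    "build_library",
    "complete_codons",
    "enumerate_aa_substitutions",
    "enumerate_indels",
    "enumerate_snvs",
    "min_hamming_codon",
    "silence_motif",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"
_KIND_RANK = {"substitution": 0, "deletion": 1, "insertion": 2}


class UnsilenceableMotifError(ValueError):
    """No synonymous change can remove a coding motif occurrence."""


class NoVariantError(ValueError):
    """The requested codon exchange does not exist (e.g. Met/Trp synonym)."""


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def min_hamming_codon(
    ref_codon: str,
    target_aa: str,
    tie_rule: Callable[[list[str]], str] | str = "lexicographic",
) -> str:
    """Codon encoding *target_aa* with minimal Hamming distance to *ref_codon*.

    Ties are broken by ``tie_rule``: the default picks the
    lexicographically smallest codon; a callable receives the sorted list
    of tied codons and returns one of them.
    """
    ref_codon = ref_codon.upper()
    if target_aa not in CODONS_BY_AA:
        raise ValueError(f"unknown amino acid {target_aa!r}")
    candidates = [c for c in CODONS_BY_AA[target_aa] if c != ref_codon]
    if not candidates:
        raise NoVariantError(f"no alternative codon encodes {target_aa!r}")
    dmin = min(_hamming(ref_codon, c) for c in candidates)
    tied = sorted(c for c in candidates if _hamming(ref_codon, c) == dmin)
    if tie_rule == "lexicographic":
        return tied[0]
    if callable(tie_rule):
        return tie_rule(tied)
    raise ValueError(f"unknown tie rule {tie_rule!r}")


def enumerate_snvs(region_sequence: str) -> list[Edit]:
    """All 3L single-nucleotide substitutions of an L-nt region."""
    return [
        Edit("substitution", i, base, alt)
        for i, base in enumerate(region_sequence)
        for alt in _BASES
        if alt != base
    ]


def enumerate_indels(region_sequence: str, max_del: int = 3) -> list[Edit]:
    """All left-aligned 1-nt insertions and 1..max_del-nt deletions.

    Returns the raw edit set (4L insertions, sum of L-s+1 deletions per
    size); edits producing identical sequences are collapsed downstream.
    """
    seq = region_sequence
    L = len(seq)
    edits: list[Edit] = []
    for i in range(L):
        for b in _BASES:
            p = i
            while p > 0 and seq[p - 1] == b:
                p -= 1
            edits.append(Edit("insertion", p, "", b))
    for size in range(1, max_del + 1):
        for i in range(L - size + 1):
            p = i
            while p > 0 and seq[p - 1] == seq[p + size - 1]:
                p -= 1
            edits.append(Edit("deletion", p, seq[p : p + size], ""))
    return edits


def complete_codons(model: TranscriptModel, region: int) -> list[tuple[int, int]]:
    """Codons lying entirely within the region's exon.

    Returns ``(cds_codon_index, region_offset)`` pairs; codons spanning
    exon boundaries cannot be mutagenized within a single region and are
    excluded.
    """
    vs, _ = model.variable_interval(region)
    s, e = model.exons[region]
    out = []
    for g in range(s, e - 2):
        cds_pos = model.genomic_to_cds(g)
        if cds_pos is None or cds_pos % 3 != 0:
            continue
        if g + 3 <= e:  # codon fully inside this exon
            out.append((cds_pos // 3, g - vs))
    return out


def enumerate_aa_substitutions(
    model: TranscriptModel,
    region: int,
    include_synonymous: bool = True,
    tie_rule: Callable[[list[str]], str] | str = "lexicographic",
) -> list[Edit]:
    """Multi-nucleotide codon substitutions completing the amino-acid scan.

    For every complete codon, targets not reachable by any single-
    nucleotide substitution (among the 19 missense amino acids, STOP and
    optionally a synonymous codon) are generated via
    :func:`min_hamming_codon`.  Amino acids encoded by a single codon
    (Met, Trp) have no synonymous entry.
    """
    region_seq = model.variable_sequence(region)
    edits: list[Edit] = []
    for codon_idx, offset in complete_codons(model, region):
        ref = region_seq[offset : offset + 3]
        wt_aa = CODON_TO_AA[ref]
        reachable = {
            CODON_TO_AA[ref[:i] + b + ref[i + 1 :]]
            for i in range(3)
            for b in _BASES
            if b != ref[i]
        }
        targets = set(AMINO_ACIDS) | {"*"}
        if not include_synonymous or len(CODONS_BY_AA.get(wt_aa, [])) < 2:
            targets.discard(wt_aa)
        for target in sorted(targets):
            if target in reachable:
                continue  # covered by the SNV enumeration
            try:
                alt = min_hamming_codon(ref, target, tie_rule)
            except NoVariantError:
                continue
            first = next(i for i in range(3) if ref[i] != alt[i])
            last = next(i for i in range(2, -1, -1) if ref[i] != alt[i])
            edits.append(
                Edit(
                    "substitution",
                    offset + first,
                    ref[first : last + 1],
                    alt[first : last + 1],
                )
            )
    return edits


# ---------------------------------------------------------------------
# restriction-site silencing


def _occurrences(seq: str, motifs: Iterable[str]) -> list[int]:
    hits = []
    for m in motifs:
        start = 0
        while True:
            i = seq.find(m, start)
            if i < 0:
                break
            hits.append(i)
            start = i + 1
    return sorted(set(hits))


def silence_motif(model: TranscriptModel, motif: str = "GAAGAC") -> TranscriptModel:
    """Remove every occurrence of *motif* (and its reverse complement).

    Coding occurrences are removed by the first synonymous codon swap
    (scanning codons 5'->3', alternative codons in alphabetical order)
    that eliminates the site without creating a new one; intronic
    occurrences by the first single-base change (position 5'->3', bases
    alphabetical) with the same guarantee.  The protein is unchanged.
    """
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 nt")
    motifs = {motif, reverse_complement(motif)}
    seq = model.sequence
    protein = model.protein()
    dinucs = model.splice_dinucleotide_positions()
    exonic = [False] * len(seq)
    for s, e in model.exons:
        for p in range(s, e):
            exonic[p] = True

    for _ in range(100):  # guard against cycles
        occ = _occurrences(seq, motifs)
        if not occ:
            break
        site = occ[0]
        span = range(site, site + len(motif))
        before = set(occ)
        candidate = None

        # 1) synonymous codon swap for coding overlap
        for g in span:
            if not exonic[g]:
                continue
            cds_pos = model.genomic_to_cds(g)
            if cds_pos is None:
                continue
            codon_i = cds_pos // 3
            codon_g = g - (cds_pos % 3)
            if codon_g < 0 or codon_g + 3 > len(seq):
                continue
            if not all(exonic[p] for p in range(codon_g, codon_g + 3)):
                continue
            ref = seq[codon_g : codon_g + 3]
            for alt in CODONS_BY_AA.get(CODON_TO_AA[ref], []):
                if alt == ref:
                    continue
                trial = seq[:codon_g] + alt + seq[codon_g + 3 :]
                after = set(_occurrences(trial, motifs))
                if site not in after and after <= before - {site}:
                    candidate = trial
                    break
            if candidate:
                break

        # 2) single intronic base change
        if candidate is None:
            for g in span:
                if exonic[g] or g in dinucs:
                    continue
                for b in _BASES:
                    if b == seq[g]:
                        continue
                    trial = seq[:g] + b + seq[g + 1 :]
                    after = set(_occurrences(trial, motifs))
                    if site not in after and after <= before - {site}:
                        candidate = trial
                        break
                if candidate:
                    break

        if candidate is None:
            raise UnsilenceableMotifError(
                f"cannot remove motif occurrence at position {site}"
            )
        seq = candidate

    silenced = replace(model, sequence=seq)
    if silenced.protein() != protein:
        raise UnsilenceableMotifError("motif silencing altered the protein")
    return silenced


# ---------------------------------------------------------------------
# assembled library


@dataclass(frozen=True)
class VariantRecord:
    variant_id: str
    region: int
    edit: Edit
    sequence: str
    consequence: Consequence
    hamming_to_wt: Optional[int] = None


@dataclass
class DesignConfig:
    """Enumeration switches mirroring the library construction protocol."""

    snvs: bool = True
    aa_substitutions: bool = True
    insertions: bool = True
    deletions: bool = True
    max_del: int = 3
    include_synonymous: bool = True
    tie_rule: str = "lexicographic"


@dataclass
class LibraryTable:
    records: list[VariantRecord]
    wt_sequences: dict[int, str]
    design_config: DesignConfig = field(default_factory=DesignConfig)

    def __len__(self) -> int:
        return len(self.records)

    def region_records(self, region: int) -> list[VariantRecord]:
        return [r for r in self.records if r.region == region]

    def sequence_index(self, region: int) -> dict[str, str]:
        """Map full variable-region sequence -> variant_id."""
        return {r.sequence: r.variant_id for r in self.records if r.region == region}

    def ids_by_class(self, coding_class: str) -> set[str]:
        return {
            r.variant_id
            for r in self.records
            if r.consequence.coding_class == coding_class
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            c = r.consequence
            rows.append(
                {
                    "variant_id": r.variant_id,
                    "region": r.region,
                    "kind": r.edit.kind,
                    "pos": r.edit.pos,
                    "ref": r.edit.ref,
                    "alt": r.edit.alt,
                    "sequence": r.sequence,
                    "coding_class": c.coding_class,
                    "nt_class": c.nt_class,
                    "protein_change": c.protein_change,
                    "codon_index": c.codon_index,
                    "introduces_ptc": c.introduces_ptc,
                    "spans_boundary": c.spans_boundary,
                    "hamming_to_wt": r.hamming_to_wt,
                }
            )
        return pd.DataFrame(rows).set_index("variant_id")


def _variant_id(region: int, edit: Edit) -> str:
    if edit.kind == "substitution":
        return f"r{region}:s{edit.pos}:{edit.ref}>{edit.alt}"
    if edit.kind == "deletion":
        return f"r{region}:d{edit.pos}:-{edit.ref}"
    return f"r{region}:i{edit.pos}:+{edit.alt}"


def build_library(model: TranscriptModel, config: Optional[DesignConfig] = None) -> LibraryTable:
    """Enumerate, deduplicate and annotate the full variant library.

    A sequence reachable by several edits keeps a single record; the
    retained annotation follows the precedence substitution > deletion >
    insertion, then the 5'-most position, then alphabetical alternative
    -- the simplest mutational explanation of that sequence.
    """
    config = config or DesignConfig()
    records: list[VariantRecord] = []
    wt_sequences: dict[int, str] = {}
    for region in range(model.n_regions):
        wt = model.variable_sequence(region)
        wt_sequences[region] = wt
        if len(wt) < max(3, config.max_del):
            warnings.warn(f"region {region} too short for full enumeration", UserWarning)
        edits: list[Edit] = []
        if config.snvs:
            edits.extend(enumerate_snvs(wt))
        if config.aa_substitutions:
            edits.extend(
                enumerate_aa_substitutions(
                    model, region, config.include_synonymous, config.tie_rule
                )
            )
        if config.insertions or config.deletions:
            for e in enumerate_indels(wt, config.max_del):
                if e.kind == "insertion" and config.insertions:
                    edits.append(e)
                elif e.kind == "deletion" and config.deletions:
                    edits.append(e)

        best: dict[str, Edit] = {}
        for e in edits:
            seq = apply_edit(wt, e)
            if not seq or seq == wt:
                continue  # degenerate or WT-restoring edit
            key = (_KIND_RANK[e.kind], e.pos, e.alt or e.ref)
            prev = best.get(seq)
            if prev is None or key < (_KIND_RANK[prev.kind], prev.pos, prev.alt or prev.ref):
                best[seq] = e

        for seq, e in sorted(
            best.items(), key=lambda kv: (_KIND_RANK[kv[1].kind], kv[1].pos, kv[0])
        ):
            cons = annotate_edit(e, model, region)
            records.append(
                VariantRecord(
                    variant_id=_variant_id(region, e),
                    region=region,
                    edit=e,
                    sequence=seq,
                    consequence=cons,
                    hamming_to_wt=_hamming(wt, seq) if e.kind == "substitution" else None,
                )
            )
    return LibraryTable(records=records, wt_sequences=wt_sequences, design_config=config)
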