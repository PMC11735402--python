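"""Transcript/mini-gene representation, splicing and consequence annotation.

The model describes a genomic segment in transcript-strand orientation:
a nucleotide sequence with exon intervals (0-based, half-open), a CDS
start offset on the spliced sequence, and the protein position of the
first complete codon.  Each exon together with ``flank_len`` intronic
nucleotides on either side forms one *variable region* -- the mutagenized
unit of a saturation genome editing library -- framed by ``constant_len``
nucleotides of constant sequence used for amplicon anchoring.

All coordinates are 0-based half-open internally; 1-based HGVS-like
protein labels appear only in output strings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

from Bio.Data import CodonTable

__all__ = [
    "AlphabetError",
    "Consequence",
    "Edit",
    "InvalidModelError",
    "SpliceWarning",
    "TranscriptModel",
    "annotate_edit",
    "apply_edit",
    "build_transcript_model",
    "reverse_complement",
    "translate",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> single-letter amino acid, stop codons mapped to ``*``
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino acid (or ``*``) -> sorted list of codons
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_PURINES = frozenset("AG")
_DNA = frozenset("ACGT")

CODING_CLASSES = (
    "synonymous",
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "intronic",
    "splice_dinucleotide",
)
NT_CLASSES = ("sub1_Ts", "sub1_Tv", "sub2", "sub3", "ins", "del_if", "del_fs", "intronic")


class InvalidModelError(ValueError):
    """Raised for inconsistent exon structure or degenerate CDS."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside A/C/G/T."""


class SpliceWarning(UserWarning):
    """Emitted when an intron violates the canonical GT..AG rule."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide string codon by codon (trailing bases ignored)."""
    n = len(seq) - len(seq) % 3
    return "".join(CODON_TO_AA[seq[i : i + 3]] for i in range(0, n, 3))


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - _DNA
    if bad:
        raise AlphabetError(f"non-ACGT characters in sequence: {sorted(bad)}")


@dataclass(frozen=True)
class Edit:
    """A single edit expressed in variable-region coordinates.

    ``pos`` is the 0-based offset within the variable region.  For an
    insertion the single base ``alt`` is inserted *before* ``pos`` and
    ``ref`` is empty; for a deletion ``alt`` is empty.  Indels are
    expected left-aligned (VCF-style) within the region.
    """

    kind: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.pos < 0:
            raise ValueError("edit position must be non-negative")
        _check_alphabet(self.ref + self.alt)
        if self.kind == "substitution":
            if len(self.ref) != len(self.alt) or not 1 <= len(self.ref) <= 3:
                raise ValueError("substitution requires len(ref) == len(alt) in 1..3")
            if self.ref == self.alt:
                raise ValueError("substitution must change the sequence")
        elif self.kind == "insertion":
            if self.ref or len(self.alt) != 1:
                raise ValueError("insertion requires empty ref and a single alt base")
        else:  # deletion
            if self.alt or not 1 <= len(self.ref) <= 3:
                raise ValueError("deletion requires empty alt and 1..3 ref bases")

    @property
    def span(self) -> tuple[int, int]:
        """Reference interval affected by the edit (empty for insertions)."""
        return (self.pos, self.pos + len(self.ref))


@dataclass(frozen=True)
class Consequence:
    """Deterministic functional annotation of one edit."""

    coding_class: str
    nt_class: str
    protein_change: str
    codon_index: Optional[int]
    introduces_ptc: bool
    spans_boundary: bool = False


@dataclass
class TranscriptModel:
    name: str
    sequence: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int = 0
    codon_offset: int = 1
    flank_len: int = 12
    constant_len: int = 13

    def __post_init__(self) -> None:
        _check_alphabet(self.sequence)
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e <= len(self.sequence)):
                raise InvalidModelError(f"exon ({s}, {e}) out of range")
            if s <= prev_end:
                raise InvalidModelError("exons must be sorted and disjoint")
            prev_end = e
        if not self.exons:
            raise InvalidModelError("at least one exon is required")
        for i_start, i_end in self.introns():
            intron = self.sequence[i_start:i_end]
            if len(intron) < 4 or not (intron.startswith("GT") and intron.endswith("AG")):
                warnings.warn(
                    f"{self.name}: intron [{i_start}, {i_end}) violates GT..AG rule",
                    SpliceWarning,
                    stacklevel=2,
                )
        if len(self.cds()) < 3:
            raise InvalidModelError("spliced CDS shorter than one codon")

    # -- structure -----------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]

    def splice_dinucleotide_positions(self) -> frozenset[int]:
        """Genomic positions of the invariant GT/AG intron dinucleotides."""
        pos: set[int] = set()
        for s, e in self.introns():
            pos.update((s, s + 1, e - 2, e - 1))
        return frozenset(pos)

    def variable_interval(self, region: int) -> tuple[int, int]:
        s, e = self.exons[region]
        return (max(0, s - self.flank_len), min(len(self.sequence), e + self.flank_len))

    def variable_sequence(self, region: int) -> str:
        vs, ve = self.variable_interval(region)
        return self.sequence[vs:ve]

    def constant_flanks(self, region: int) -> tuple[str, str]:
        vs, ve = self.variable_interval(region)
        return (
            self.sequence[max(0, vs - self.constant_len) : vs],
            self.sequence[ve : ve + self.constant_len],
        )

    # -- splicing / translation ---------------------------------------

    def spliced(self, sequence: Optional[str] = None, exons=None) -> str:
        seq = self.sequence if sequence is None else sequence
        exons = self.exons if exons is None else exons
        return "".join(seq[s:e] for s, e in exons)

    def cds(self, sequence: Optional[str] = None, exons=None) -> str:
        return self.spliced(sequence, exons)[self.cds_start :]

    def protein(self) -> str:
        return translate(self.cds())

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """Map a genomic position to its CDS offset, None if non-coding."""
        spliced_pos = 0
        for s, e in self.exons:
            if s <= pos < e:
                idx = spliced_pos + (pos - s)
                return idx - self.cds_start if idx >= self.cds_start else None
            spliced_pos += e - s
        return None


def build_transcript_model(
    sequence: str,
    exons,
    cds_start: int = 0,
    codon_offset: int = 1,
    flank_len: int = 12,
    constant_len: int = 13,
    name: str = "model",
) -> TranscriptModel:
    """Validate inputs and assemble a :class:`TranscriptModel`."""
    return TranscriptModel(
        name=name,
        sequence=sequence.upper(),
        exons=tuple(tuple(x) for x in exons),
        cds_start=cds_start,
        codon_offset=codon_offset,
        flank_len=flank_len,
        constant_len=constant_len,
    )


def apply_edit(region_sequence: str, edit: Edit) -> str:
    """Apply an edit to a variable-region sequence and return the result."""
    pos, end = edit.span
    if end > len(region_sequence) or (edit.kind == "insertion" and pos >= len(region_sequence) + 1):
        raise ValueError("edit outside region bounds")
    if region_sequence[pos:end] != edit.ref:
        raise ValueError(
            f"edit ref {edit.ref!r} does not match region sequence "
            f"{region_sequence[pos:end]!r} at {pos}"
        )
    return region_sequence[:pos] + edit.alt + region_sequence[end:]


def _shift_boundary(x: int, pos: int, end: int, delta: int, is_start: bool) -> int:
    """Map a WT exon boundary coordinate into the edited sequence.

    Positions inside a deleted span collapse to its start.  An insertion
    exactly at an exon boundary is assigned to the intronic side.
    """
    if pos == end:  # insertion point
        if is_start:
            return x + delta if x >= pos else x
        return x + delta if x > pos else x
    if x <= pos:
        return x
    if x >= end:
        return x + delta
    return pos  # collapsed into the edited span


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _substitution_nt_class(ref: str, alt: str, exonic: bool) -> str:
    if not exonic:
        return "intronic"
    h = _hamming(ref, alt)
    if h >= 3:
        return "sub3"
    if h == 2:
        return "sub2"
    # locate the single changed base
    i = next(k for k in range(len(ref)) if ref[k] != alt[k])
    same_group = (ref[i] in _PURINES) == (alt[i] in _PURINES)
    return "sub1_Ts" if same_group else "sub1_Tv"


def annotate_edit(edit: Edit, model: TranscriptModel, region: int) -> Consequence:
    """Classify an edit by re-splicing and re-translating the edited gene.

    Substitutions touching only intronic positions (outside the splice
    dinucleotides) are ``intronic``; disruption of an invariant GT/AG
    dinucleotide takes precedence over any coding classification.  Edits
    that touch both exonic and intronic sequence are classified by their
    exonic effect and flagged with ``spans_boundary``.
    """
    vs, ve = model.variable_interval(region)
    pos = vs + edit.pos
    end = pos + len(edit.ref)
    if not (vs <= pos and end <= ve):
        raise ValueError(f"edit {edit} outside variable region [{vs}, {ve})")
    if edit.kind == "insertion" and pos >= ve:
        raise ValueError("insertion anchor outside variable region")

    seq = model.sequence
    if seq[pos:end] != edit.ref:
        raise ValueError(f"edit ref mismatch at genomic position {pos}")
    edited = seq[:pos] + edit.alt + seq[end:]
    delta = len(edit.alt) - len(edit.ref)
    new_exons = tuple(
        (
            _shift_boundary(s, pos, end, delta, True),
            _shift_boundary(e, pos, end, delta, False),
        )
        for s, e in model.exons
    )

    affected = range(pos, end)  # empty for insertions
    exon_positions = lambda p: any(s <= p < e for s, e in model.exons)  # noqa: E731
    if edit.kind == "insertion":
        # the inserted base lands inside an exon only strictly between its ends
        exon_overlap = any(s < pos < e for s, e in model.exons)
        intron_overlap = not exon_overlap
    else:
        exon_overlap = any(exon_positions(p) for p in affected)
        intron_overlap = any(not exon_positions(p) for p in affected)

    dinucs = model.splice_dinucleotide_positions()
    dinuc_pairs = [(s, s + 1) for s, e in model.introns()] + [
        (e - 2, e - 1) for s, e in model.introns()
    ]
    if edit.kind == "insertion":
        # disrupts a dinucleotide only when inserted between its two bases
        splice_hit = any(pos == d1 for _, d1 in dinuc_pairs)
    else:
        splice_hit = any(p in dinucs for p in affected)

    wt_cds = model.cds()
    wt_prot = translate(wt_cds)
    ed_cds = model.cds(edited, new_exons)
    ed_prot = translate(ed_cds)

    # -- nt class ------------------------------------------------------
    if edit.kind == "substitution":
        nt_class = _substitution_nt_class(edit.ref, edit.alt, exon_overlap)
    elif edit.kind == "insertion":
        nt_class = "ins" if exon_overlap else "intronic"
    else:
        if not exon_overlap:
            nt_class = "intronic"
        else:
            nt_class = "del_if" if (len(ed_cds) - len(wt_cds)) % 3 == 0 else "del_fs"

    # -- PTC: first stop earlier than in the WT frame ------------------
    wt_stop = wt_prot.find("*")
    wt_stop = len(wt_prot) if wt_stop < 0 else wt_stop
    ed_stop = ed_prot.find("*")
    introduces_ptc = ed_stop >= 0 and ed_stop < wt_stop

    # -- coding class --------------------------------------------------
    codon_index: Optional[int] = None
    protein_change = "="
    if splice_hit:
        coding_class = "splice_dinucleotide"
    elif not exon_overlap:
        coding_class = "intronic"
    else:
        dl = len(ed_cds) - len(wt_cds)
        first_exonic = next((p for p in affected if exon_positions(p)), pos)
        cds_pos = model.genomic_to_cds(first_exonic)
        codon_i = None if cds_pos is None else cds_pos // 3
        if codon_i is not None:
            codon_index = model.codon_offset + codon_i
        if dl % 3 != 0:
            coding_class = "frameshift"
            if codon_i is not None and codon_i < len(wt_prot):
                protein_change = f"{wt_prot[codon_i]}{codon_index}fs"
        elif dl != 0:
            coding_class = "inframe_indel"
            if codon_i is not None and codon_i < len(wt_prot):
                tag = "del" if dl < 0 else "ins"
                protein_change = f"{wt_prot[codon_i]}{codon_index}{tag}"
        else:
            diffs = [i for i in range(min(len(wt_prot), len(ed_prot))) if wt_prot[i] != ed_prot[i]]
            if not diffs:
                coding_class = "synonymous"
            elif any(ed_prot[i] == "*" for i in diffs):
                coding_class = "nonsense"
            else:
                coding_class = "missense"
            if diffs:
                codon_index = model.codon_offset + diffs[0]
                protein_change = "/".join(
                    f"{wt_prot[i]}{model.codon_offset + i}{ed_prot[i]}" for i in diffs
                )
            # synonymous keeps protein_change "=", but report the codon touched
            if coding_class == "synonymous" and cds_pos is not None:
                codon_index = model.codon_offset + codon_i

    return Consequence(
        coding_class=coding_class,
        nt_class=nt_class,
        protein_change=protein_change,
        codon_index=codon_index,
        introduces_ptc=introduces_ptc,
        spans_boundary=exon_overlap and intron_overlap,
    )


def model_with_sequence(model: TranscriptModel, sequence: str) -> TranscriptModel:
    """Return a copy of *model* with a substituted (equal-length) sequence."""
    if len(sequence) != len(model.sequence):
        raise ValueError("replacement sequence must have the same length")
    return replace(model, sequence=sequence)
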