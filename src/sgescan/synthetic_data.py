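"""Synthetic mini-genes, true fitness assignments and screen simulation.

The generator emulates the statistical structure of a saturation genome
editing proliferation screen: a multi-exon mini-gene with GT..AG introns
and intronic flanks, per-variant true fitness drawn by consequence class
(nonsense/frameshift high near +1, synonymous/intronic low near -1,
missense a two-component LOF/WT-like mixture), replicate count tables
under exponential selection with multinomial sequencing noise, and mRNA
tables in which premature-termination-codon (PTC) variants are depleted
by a configurable fold (default 30) to mimic nonsense-mediated decay.

All randomness flows from ``SimulationConfig.seed``; identical configs
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from sgescan.counting import CountMatrix
from sgescan.library_design import LibraryTable
from sgescan.seqmodel import CODON_TO_AA, TranscriptModel, build_transcript_model

__all__ = [
    "SimulationConfig",
    "assign_true_fitness",
    "emit_reads",
    "make_minigene",
    "simulate_mrna",
    "simulate_screen",
]

_NONSTOP_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
_BASES = np.array(list("ACGT"))

#: default per-class fitness distributions (mean, sd) on the RFS-like
#: scale where -1 is synonymous-like and +1 nonsense-like
DEFAULT_CLASS_PARAMS: dict[str, tuple[float, float]] = {
    "nonsense": (1.0, 0.1),
    "frameshift": (1.0, 0.1),
    "splice_dinucleotide": (1.0, 0.1),
    "inframe_indel": (0.8, 0.3),
    "synonymous": (-1.0, 0.1),
    "intronic": (-1.0, 0.15),
    "missense_lof": (1.0, 0.3),
    "missense_wt": (-1.0, 0.3),
}


@dataclass
class SimulationConfig:
    """Study conditions of the simulated screen.

    ``depth`` is the expected read count per variant (coverage of at
    least 500 edited cells per variant in the emulated experiment);
    ``selection_strength`` g scales the exponential enrichment
    2**(g * fitness) under treatment; ``nmd_fold`` is the realized
    mRNA/DNA abundance fold depletion of PTC variants; ``dispersion`` is
    the per-variant Dirichlet concentration perturbing the initial
    abundances (clone-size variation).
    """

    seed: int = 0
    n_exons: int = 2
    exon_len: int = 60
    intron_len: int = 30
    depth: float = 500.0
    replicates: int = 3
    selection_strength: float = 2.0
    class_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    missense_lof_weight: float = 0.55
    nmd_fold: float = 30.0
    mrna_depth: Optional[float] = None
    dispersion: float = 50.0
    flank_len: int = 12
    constant_len: int = 13
    read_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.missense_lof_weight <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")
        if self.exon_len < 9 or self.intron_len < 6:
            raise ValueError("exon_len >= 9 and intron_len >= 6 required")
        if (self.n_exons * self.exon_len) % 3 != 0:
            raise ValueError("total exonic length must be a multiple of 3")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named sub-stream."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def make_minigene(config: SimulationConfig) -> TranscriptModel:
    """Random mini-gene with GT..AG introns and a stop-free reading frame."""
    rng = config.rng(0)
    n_codons = config.n_exons * config.exon_len // 3
    codons = ["ATG"] + list(rng.choice(_NONSTOP_CODONS, size=n_codons - 1))
    cds = "".join(codons)

    def random_nt(n: int) -> str:
        return "".join(rng.choice(_BASES, size=n))

    parts = [random_nt(config.intron_len)]  # 5' pad so the first exon has a flank
    exons = []
    pos = config.intron_len
    for i in range(config.n_exons):
        exon = cds[i * config.exon_len : (i + 1) * config.exon_len]
        parts.append(exon)
        exons.append((pos, pos + config.exon_len))
        pos += config.exon_len
        if i < config.n_exons - 1:
            intron = "GT" + random_nt(config.intron_len - 4) + "AG"
            parts.append(intron)
            pos += config.intron_len
    parts.append(random_nt(config.intron_len))  # 3' pad
    return build_transcript_model(
        "".join(parts),
        exons,
        cds_start=0,
        codon_offset=1,
        flank_len=config.flank_len,
        constant_len=config.constant_len,
        name=f"minigene_seed{config.seed}",
    )


def assign_true_fitness(library: LibraryTable, config: SimulationConfig) -> pd.DataFrame:
    """Per-variant ground truth: fitness, class label and PTC status.

    Missense variants draw a component (LOF with probability
    ``missense_lof_weight``); splice-dinucleotide variants are forced
    LOF.  Returns a frame indexed by variant_id with columns
    ``true_fitness``, ``true_class``, ``component`` and ``is_ptc``.
    """
    rng = config.rng(1)
    rows = []
    for rec in library.records:
        cls = rec.consequence.coding_class
        if cls == "missense":
            lof = rng.random() < config.missense_lof_weight
            component = "lof" if lof else "wt_like"
            mean, sd = config.class_params["missense_lof" if lof else "missense_wt"]
        else:
            mean, sd = config.class_params.get(cls, (0.0, 0.2))
            component = "lof" if mean > 0 else "wt_like"
        fitness = rng.normal(mean, sd) if sd > 0 else mean
        rows.append(
            {
                "variant_id": rec.variant_id,
                "true_fitness": fitness,
                "true_class": cls,
                "component": component,
                "is_ptc": bool(rec.consequence.introduces_ptc),
            }
        )
    return pd.DataFrame(rows).set_index("variant_id")


def _dirichlet_abundance(rng: np.random.Generator, n: int, concentration: float) -> np.ndarray:
    if concentration <= 0:
        return np.full(n, 1.0 / n)
    return rng.dirichlet(np.full(n, concentration))


def simulate_screen(
    library: LibraryTable,
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> CountMatrix:
    """Replicate control/treated DNA count tables under selection.

    Per replicate, the initial abundance vector is a Dirichlet
    perturbation of uniform; the treated expectation is proportional to
    f0 * 2**(g * fitness); both samples draw depth * n_variants reads
    multinomially.
    """
    ids = [r.variant_id for r in library.records]
    fitness = truth.loc[ids, "true_fitness"].to_numpy()
    n = len(ids)
    total = int(round(config.depth * n))
    g = config.selection_strength

    cols: dict[str, np.ndarray] = {}
    meta = []
    for rep in range(1, config.replicates + 1):
        rng = config.rng(10 + rep)
        f0 = _dirichlet_abundance(rng, n, config.dispersion)
        p_treated = f0 * np.power(2.0, g * fitness)
        p_treated /= p_treated.sum()
        cols[f"control_rep{rep}"] = rng.multinomial(total, f0)
        cols[f"treated_rep{rep}"] = rng.multinomial(total, p_treated)
        meta.append({"sample": f"control_rep{rep}", "condition": "control", "replicate": rep, "material": "DNA"})
        meta.append({"sample": f"treated_rep{rep}", "condition": "treated", "replicate": rep, "material": "DNA"})

    counts = pd.DataFrame(cols, index=pd.Index(ids, name="variant_id"))
    samples = pd.DataFrame(meta).set_index("sample")
    return CountMatrix(counts=counts, samples=samples)


def simulate_mrna(
    dna_counts: CountMatrix,
    truth: pd.DataFrame,
    config: SimulationConfig,
    condition: str = "control",
) -> CountMatrix:
    """mRNA count tables with PTC variants depleted ``nmd_fold``-fold.

    The depletion is calibrated so that the *observed* mRNA/DNA relative
    abundance ratio of PTC variants equals 1/nmd_fold after the mRNA
    pool is renormalized -- matching how NMD depletion is measured.
    Non-PTC variants gain the complementary renormalization factor
    (slightly above 1).
    """
    k = float(config.nmd_fold)
    if k < 1:
        raise ValueError("nmd_fold must be >= 1")
    cols = dna_counts.columns_for(condition=condition, material="DNA")
    if not cols:
        raise ValueError(f"no DNA columns with condition {condition!r}")
    ids = dna_counts.counts.index
    is_ptc = truth.loc[ids, "is_ptc"].to_numpy(dtype=bool)

    out: dict[str, np.ndarray] = {}
    meta = []
    for j, col in enumerate(cols):
        rng = config.rng(100 + j)
        dna = dna_counts.counts[col].to_numpy(dtype=float)
        f_dna = dna / dna.sum()
        p_mass = f_dna[is_ptc].sum()
        if k == 1.0:
            mult = 1.0
        else:
            z = (1.0 - p_mass) / (1.0 - p_mass / k)
            mult = z / k
        f = np.where(is_ptc, f_dna * mult, f_dna)
        f /= f.sum()
        depth = config.mrna_depth if config.mrna_depth is not None else config.depth
        total = int(round(depth * len(ids)))
        rep = int(dna_counts.samples.loc[col, "replicate"])
        name = f"mrna_rep{rep}"
        out[name] = rng.multinomial(total, f)
        meta.append({"sample": name, "condition": condition, "replicate": rep, "material": "mRNA"})

    counts = pd.DataFrame(out, index=ids)
    samples = pd.DataFrame(meta).set_index("sample")
    return CountMatrix(counts=counts, samples=samples)


def emit_reads(
    library: LibraryTable,
    counts: pd.Series,
    model: TranscriptModel,
    region: int,
    rng: Optional[np.random.Generator] = None,
    error_rate: float = 0.0,
    n_wt: int = 0,
) -> Iterator[str]:
    """Emit merged reads (flank5 + variant + flank3) for one sample column.

    With ``error_rate`` 0 (default) exact-match counting recovers the
    input counts losslessly.
    """
    flank5, flank3 = model.constant_flanks(region)
    wt = library.wt_sequences[region]
    by_id = {r.variant_id: r.sequence for r in library.records if r.region == region}

    def mutate(seq: str) -> str:
        if error_rate <= 0 or rng is None:
            return seq
        arr = np.array(list(seq))
        hit = rng.random(len(arr)) < error_rate
        for i in np.nonzero(hit)[0]:
            arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
        return "".join(arr)

    for vid, c in counts.items():
        seq = by_id.get(vid)
        if seq is None:
            continue
        read = flank5 + seq + flank3
        for _ in range(int(c)):
            yield mutate(read)
    for _ in range(n_wt):
        yield mutate(flank5 + wt + flank3)
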