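"""File I/O: transcript models (FASTA + YAML sidecar), library tables
(TSV/FASTA), count tables and evaluation reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from sgescan.library_design import DesignConfig, LibraryTable, VariantRecord
from sgescan.seqmodel import Consequence, Edit, TranscriptModel, build_transcript_model

__all__ = [
    "read_library_tsv",
    "read_model",
    "write_library_fasta",
    "write_library_tsv",
    "write_model",
]


def write_model(model: TranscriptModel, fasta_path: str | Path, yaml_path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(model.sequence), id=model.name, description="")],
        str(fasta_path),
        "fasta",
    )
    sidecar = {
        "name": model.name,
        "exons": [list(x) for x in model.exons],
        "cds_start": model.cds_start,
        "codon_offset": model.codon_offset,
        "flank_len": model.flank_len,
        "constant_len": model.constant_len,
    }
    Path(yaml_path).write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_model(fasta_path: str | Path, yaml_path: str | Path) -> TranscriptModel:
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    meta = yaml.safe_load(Path(yaml_path).read_text())
    return build_transcript_model(
        str(record.seq),
        meta["exons"],
        cds_start=meta.get("cds_start", 0),
        codon_offset=meta.get("codon_offset", 1),
        flank_len=meta.get("flank_len", 12),
        constant_len=meta.get("constant_len", 13),
        name=meta.get("name", record.id),
    )


def write_library_tsv(library: LibraryTable, path: str | Path) -> None:
    frame = library.to_frame()
    frame.insert(0, "wt_sequence", [library.wt_sequences[r] for r in frame["region"]])
    frame.to_csv(path, sep="\t")


def write_library_fasta(
    library: LibraryTable,
    path: str | Path,
    model: Optional[TranscriptModel] = None,
    with_constant_frames: bool = False,
) -> None:
    """Library FASTA (id = variant_id); optionally as full oligos with
    constant frames prepended/appended."""
    records = []
    for rec in library.records:
        seq = rec.sequence
        if with_constant_frames:
            if model is None:
                raise ValueError("model required for constant frames")
            f5, f3 = model.constant_flanks(rec.region)
            seq = f5 + seq + f3
        records.append(SeqRecord(Seq(seq), id=rec.variant_id, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_library_tsv(path: str | Path) -> LibraryTable:
    frame = pd.read_csv(path, sep="\t", index_col="variant_id", keep_default_na=False)
    records = []
    wt: dict[int, str] = {}
    for vid, row in frame.iterrows():
        region = int(row["region"])
        wt[region] = row["wt_sequence"]
        edit = Edit(row["kind"], int(row["pos"]), row["ref"], row["alt"])
        cons = Consequence(
            coding_class=row["coding_class"],
            nt_class=row["nt_class"],
            protein_change=row["protein_change"],
            codon_index=None if row["codon_index"] in ("", None) else int(float(row["codon_index"])),
            introduces_ptc=str(row["introduces_ptc"]) == "True",
            spans_boundary=str(row["spans_boundary"]) == "True",
        )
        hamming = row.get("hamming_to_wt", "")
        records.append(
            VariantRecord(
                variant_id=vid,
                region=region,
                edit=edit,
                sequence=row["sequence"],
                consequence=cons,
                hamming_to_wt=None if hamming in ("", None) else int(float(hamming)),
            )
        )
    return LibraryTable(records=records, wt_sequences=wt, design_config=DesignConfig())


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
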