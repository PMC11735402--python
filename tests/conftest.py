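"""Shared fixtures: a hand-checkable two-exon model and a simulated screen."""

import pytest

import sgescan as sg

# two exons of 12 nt around a canonical GT..AG intron, with 6-nt pads:
#   pad5   exon1          intron      exon2          pad3
#   CCCCCC ATGGCCGAAACC   GTAAGCATAG  TGGTACAAGGAC   CCCCCC
# spliced CDS ATGGCCGAAACCTGGTACAAGGAC -> protein MAETWYKD
TOY_SEQ = "CCCCCC" + "ATGGCCGAAACC" + "GTAAGCATAG" + "TGGTACAAGGAC" + "CCCCCC"
TOY_EXONS = [(6, 18), (28, 40)]


@pytest.fixture(scope="session")
def toy_model() -> sg.TranscriptModel:
    return sg.build_transcript_model(
        TOY_SEQ, TOY_EXONS, cds_start=0, codon_offset=1, flank_len=4, constant_len=3
    )


@pytest.fixture(scope="session")
def sim_config() -> sg.SimulationConfig:
    return sg.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def minigene(sim_config) -> sg.TranscriptModel:
    return sg.make_minigene(sim_config)


@pytest.fixture(scope="session")
def minigene_library(minigene) -> sg.LibraryTable:
    return sg.build_library(minigene)
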