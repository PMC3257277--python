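import numpy as np
import pytest

from motifswitch.core import DisorderProfile, MotifInstance, PhosphoSite, ProteinRecord


@pytest.fixture
def toy_proteome():
    """Two small proteins with known S/T/Y placement."""
    seq1 = ("MA" + "S" + "A" * 20 + "Y" + "A" * 20 + "T" + "A" * 55)  # 100 aa
    seq2 = "M" + "PAGPA" * 10 + "Y" * 2 + "A" * 47  # 100 aa
    return {
        "P1": ProteinRecord("P1", seq1),
        "P2": ProteinRecord("P2", seq2),
    }


@pytest.fixture
def flat_disorder(toy_proteome):
    return {
        acc: DisorderProfile(acc, tuple([0.8] * len(rec)))
        for acc, rec in toy_proteome.items()
    }


def make_protein(accession, sequence):
    return ProteinRecord(accession, sequence)


def make_motif(accession, start, end, family="SH3", tier="LTP", domain="D1"):
    return MotifInstance(accession, start, end, family, tier, domain)


def make_site(accession, position, residue, tier="LTP"):
    return PhosphoSite(accession, position, residue, tier, frozenset({"test"}))
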