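"""Bundled reference sequences and printed oligonucleotides.

The analysis is anchored to the four human Y RNA genes (hY1, hY3, hY4, hY5;
GenBank NR_004391, NR_004392, NR_004393, NR_001571).  The full-length
sequences bundled here are SYNTHETIC stand-ins reconstructed from the
literature-consensus hY sequences, not downloaded GenBank records; they are
provided so the pipeline runs without network access.  The 5' region of hY4
— the only stretch any numeric check in this package depends on — is fixed
independently of the reconstruction: it equals the printed EV-YF1 oligo with
its single documented position-16 T insertion removed.

EV-YF1 is a 57-nt, 5'-derived hY4 fragment, the most abundant small-RNA
species in cardiosphere-derived-cell extracellular vesicles; Ys is the
scrambled control oligo.  Both are printed as RNA and normalised U->T here.
"""

from __future__ import annotations

from .io_formats import RefSeqRecord, normalize_sequence

#: EV-YF1 oligoribonucleotide, U->T normalised (57 nt).
EV_YF1 = normalize_sequence(
    "GGCUGGUCCGAUGGUUAGUGGGUUAUCAGAACUUAUUAACAUUAGUGUCACUAAAGU"
)

#: Scrambled control oligo (Ys), U->T normalised (57 nt).
YS_SCRAMBLED = normalize_sequence(
    "GAUGUUAUUAUCGUAGUAGAUGAAUAAUCGGUGCUACGAUUAUGAGUGUCAGUCGCC"
)

#: qPCR primer pairs (forward, reverse), DNA as printed.
QPCR_PRIMERS: dict[str, tuple[str, str]] = {
    "EV-YF1": ("GGCTGGTCCGATGGTTAGTG", "ACTTTAGTGACACTAATGTT"),
    "HPRT": ("GAGAGATCATCTCCACCAAT", "ACTTTAGTGACACTAATGTT"),
    "U6": ("GCTTCGGCAGCACATATACTAAAAT", "CGCTTCACGAATTTGCGTGTCAT"),
}

# Literature-consensus human Y RNA sequences (DNA alphabet).  Synthetic
# stand-ins for the GenBank entries named in the accession field; the hY4
# 5' prefix is additionally pinned by the EV-YF1 worked alignment (see
# module docstring).
_HY_SEQUENCES: dict[str, tuple[str, str]] = {
    "hY1": (
        "NR_004391",
        "GGCTGGTCCGAAGGTAGTGAGTTATCTCAATTGATTGTTCACAGTCAGTTACAGATCGAACTCCTT"
        "GTTCTACTCTTTCCCCCCTTCTCACTACTGCACTTGACTAGTCTTTT",
    ),
    "hY3": (
        "NR_004392",
        "GGCTGGTCCGAGTGCAGTGGTGTTTACAACTAATTGATCACAACCAGTTACAGATTTCTTTGTTCC"
        "TTCTCCACTCCCACTGCTTCACTTGACTAGCCTTTT",
    ),
    "hY4": (
        "NR_004393",
        "GGCTGGTCCGATGGTAGTGGGTTATCAGAACTTATTAACATTAGTGTCACTAAAGTTGGTATACAA"
        "CCCCCCACTGCTAAATTTGACTGGCTT",
    ),
    "hY5": (
        "NR_001571",
        "AGTTGGTCCGAGTGTTGTGGGTTATTGTTAAGTTGATTTAACATTGTCTCCCCCCACAACCGCGCT"
        "TGACTAGCTTGCTGTTT",
    ),
}

#: Parent-gene identifiers in canonical order.
HY_IDS = ("hY1", "hY3", "hY4", "hY5")


def hy_reference_records() -> list[RefSeqRecord]:
    """The four full-length hY references as Y_RNA class records."""
    return [
        RefSeqRecord(id=name, accession=acc, biotype="Y_RNA",
                     sequence=normalize_sequence(seq))
        for name, (acc, seq) in _HY_SEQUENCES.items()
    ]


def hy4_record() -> RefSeqRecord:
    """Full-length hY4 (the parent of EV-YF1)."""
    return next(r for r in hy_reference_records() if r.id == "hY4")
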