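"""Nucleotide alphabet utilities shared across the package.

Genomes and FASTA files are handled in the DNA alphabet; mature miRNAs are
displayed as RNA.  The U<->T conversion is lossless and lives here so that
every module converts the same way.
"""

from __future__ import annotations

import numpy as np

_DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMPLEMENT = str.maketrans("ACGUNacgun", "UGCANugcan")

#: integer encoding used by the vectorised matchers (A=0, C=1, G=2, T/U=3, N=4)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _ENCODE[ord(base)] = i
    _ENCODE[ord(base.lower())] = i
_ENCODE[ord("U")] = 3
_ENCODE[ord("u")] = 3


def dna_to_rna(seq: str) -> str:
    """Transcribe a DNA string to RNA (T -> U), case-preserving."""
    return seq.replace("T", "U").replace("t", "u")


def rna_to_dna(seq: str) -> str:
    """Reverse-transcribe an RNA string to DNA (U -> T), case-preserving."""
    return seq.replace("U", "T").replace("u", "t")


def revcomp(seq: str) -> str:
    """Reverse complement; alphabet (DNA/RNA) inferred from the sequence.

    A sequence containing neither T nor U is treated as DNA.
    """
    table = _RNA_COMPLEMENT if ("U" in seq or "u" in seq) else _DNA_COMPLEMENT
    return seq.translate(table)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (N and unknowns -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def is_nucleotide(seq: str, alphabet: str = "ACGTUN") -> bool:
    return all(c in alphabet for c in seq.upper())
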