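"""The 21-symbol amino-acid alphabet and fast codon lookup tables.

The encoding uses the 20 standard amino acids plus a single combined
symbol ``*`` at index 20 that absorbs stop codons and any codon that
cannot be translated unambiguously (e.g. codons containing ``N``).
Keeping stops in-alphabet matters for noisy long reads: insertions and
deletions shift the reading frame, so internal stops are an expected and
informative part of a frame's translation rather than a terminator.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

#: Ordered alphabet: 20 standard residues, then the stop/ambiguity symbol.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP_SYMBOL = "*"
ALPHABET = AMINO_ACIDS + STOP_SYMBOL
ALPHABET_SIZE = len(ALPHABET)  # 21

AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
STOP_INDEX = AA_TO_INDEX[STOP_SYMBOL]

_BASES = "ACGT"
BASE_TO_INDEX = {b: i for i, b in enumerate(_BASES)}

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon string -> residue (stops collapsed to '*')
CODON_TO_AA = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = STOP_SYMBOL

#: residue -> list of synonymous codons (for reverse translation)
AA_TO_CODONS: dict[str, list[str]] = {aa: [] for aa in AMINO_ACIDS}
for _codon, _aa in sorted(_standard.forward_table.items()):
    AA_TO_CODONS[_aa].append(_codon)


def _build_codon_lut() -> np.ndarray:
    """125-entry LUT over base-5 codon indices (A,C,G,T,other) -> aa index.

    Any codon touching a non-ACGT base maps to the '*' index.
    """
    lut = np.full(125, STOP_INDEX, dtype=np.int8)
    for b0 in range(4):
        for b1 in range(4):
            for b2 in range(4):
                codon = _BASES[b0] + _BASES[b1] + _BASES[b2]
                lut[25 * b0 + 5 * b1 + b2] = AA_TO_INDEX[CODON_TO_AA[codon]]
    return lut


CODON_LUT = _build_codon_lut()

#: ASCII byte -> base-5 digit used by the codon LUT (non-ACGT -> 4).
DNA_DIGIT = np.full(256, 4, dtype=np.int64)
for _b, _i in BASE_TO_INDEX.items():
    DNA_DIGIT[ord(_b)] = _i

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def dna_to_digits(dna: str) -> np.ndarray:
    """Map a DNA string to base-5 digits (A,C,G,T -> 0..3, other -> 4)."""
    return DNA_DIGIT[np.frombuffer(dna.encode("ascii"), dtype=np.uint8)]


def complement_table() -> bytes:
    return _COMPLEMENT
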