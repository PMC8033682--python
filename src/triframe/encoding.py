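"""3-frame one-hot encoding of DNA reads.

A read of length ``L`` is translated in its three forward reading frames;
frame ``j`` yields ``floor((L - j) / 3)`` residues. Each residue is one-hot
encoded over the 21-symbol alphabet and the three frame matrices are stacked
into a ``3 x window x 21`` tensor (channel x codon position x symbol), like
the channels of an RGB image. Rows beyond a frame's translation are all-zero
padding, so pooled convolutional features are unaffected by pad length.

The reverse strand is handled by encoding the reverse complement as a second
tensor; together the two tensors cover all six reading frames of the read.
Translation never stops at stop codons: reads are fragments and frameshift
errors make internal stops ordinary, so ``*`` is emitted and translation
continues. Encoding is a pure function of the sequence.
"""

from __future__ import annotations

import warnings

import numpy as np

from .alphabet import (
    ALPHABET,
    ALPHABET_SIZE,
    CODON_LUT,
    complement_table,
    dna_to_digits,
)

DEFAULT_WINDOW = 1000  # codons; 3,000 nt, the model's fixed input span

_VALID_RC = frozenset("ACGTN")


def reverse_complement(dna: str) -> str:
    """Reverse complement over A/C/G/T/N (N maps to N)."""
    if not _VALID_RC.issuperset(dna):
        bad = sorted(set(dna) - _VALID_RC)
        raise ValueError(f"non-ACGTN symbols in sequence: {bad}")
    return dna.translate(complement_table())[::-1]


def frame_indices(dna: str, offset: int) -> np.ndarray:
    """Amino-acid indices (0..20) of the frame-``offset`` translation."""
    if offset not in (0, 1, 2):
        raise ValueError(f"frame offset must be 0, 1 or 2, got {offset}")
    digits = dna_to_digits(dna)
    n_codons = (len(dna) - offset) // 3
    if n_codons <= 0:
        return np.empty(0, dtype=np.int8)
    d = digits[offset : offset + 3 * n_codons].reshape(n_codons, 3)
    return CODON_LUT[25 * d[:, 0] + 5 * d[:, 1] + d[:, 2]]


def translate_frame(dna: str, offset: int) -> str:
    """Translate one reading frame with the standard genetic code.

    Trailing 1-2 bases are dropped; stop codons and codons containing
    non-ACGT bases emit ``*`` and translation continues.
    """
    idx = frame_indices(dna, offset)
    return "".join(ALPHABET[i] for i in idx)


def encode_3frame(dna: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Encode a read as its ``3 x window x 21`` one-hot frame tensor.

    Channel ``j`` holds the one-hot matrix of ``translate_frame(dna, j)``,
    truncated or zero-padded to ``window`` codon rows.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not dna:
        warnings.warn("encoding an empty sequence yields an all-zero tensor")
    arr = np.zeros((3, window, ALPHABET_SIZE), dtype=np.float32)
    for j in range(3):
        idx = frame_indices(dna, j)[:window]
        arr[j, np.arange(len(idx)), idx] = 1.0
    return arr


def encoded_length(dna_length: int, window: int = DEFAULT_WINDOW) -> int:
    """Number of valid codon rows (max over channels) for a read length."""
    return min(window, dna_length // 3)


def encode_batch(
    seqs: list[str], window: int = DEFAULT_WINDOW
) -> tuple[np.ndarray, np.ndarray]:
    """Encode many reads; returns (tensor batch, per-read valid row counts)."""
    batch = np.zeros((len(seqs), 3, window, ALPHABET_SIZE), dtype=np.float32)
    lengths = np.zeros(len(seqs), dtype=np.int64)
    for i, s in enumerate(seqs):
        batch[i] = encode_3frame(s, window)
        lengths[i] = encoded_length(len(s), window)
    return batch, lengths


def encode_dna_onehot(dna: str, window_nt: int) -> np.ndarray:
    """Nucleotide-level one-hot (``1 x window_nt x 4``) ablation encoding."""
    arr = np.zeros((1, window_nt, 4), dtype=np.float32)
    digits = dna_to_digits(dna)[:window_nt]
    valid = digits < 4
    arr[0, np.flatnonzero(valid), digits[valid]] = 1.0
    return arr


def crop_read(dna: str, window_nt: int = 3 * DEFAULT_WINDOW) -> list[str]:
    """Split into consecutive fragments of at most ``window_nt`` bases.

    Fragments partition the read: their concatenation reproduces the input.
    """
    if window_nt % 3 != 0:
        raise ValueError("window_nt must be a multiple of 3")
    if len(dna) <= window_nt:
        return [dna]
    return [dna[i : i + window_nt] for i in range(0, len(dna), window_nt)]
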