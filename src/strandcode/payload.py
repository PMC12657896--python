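"""Conversions between byte payloads, bit streams, nucleotide strings and strands.

Bit streams are plain ``numpy`` arrays of ``uint8`` holding 0/1 values.
Bytes are unpacked most-significant-bit first, so ``0x41`` becomes
``0,1,0,0,0,0,0,1``.  Consecutive non-overlapping bit pairs map to bases
via ``00->A, 01->C, 10->G, 11->T``; the inverse mapping decodes.  Under
this mapping a random base substitution flips one coded bit in 8 of the
12 ordered base pairs and two bits in the remaining 4 (33%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "BitStream",
    "StrandLayout",
    "bytes_to_bits",
    "bits_to_bytes",
    "bits_to_dna",
    "dna_to_bits",
    "chunk_payload",
    "reassemble_chunks",
    "PAIR_TO_BASE",
    "BASE_TO_PAIR",
]

#: Alias for readability: a 1-D uint8 array of 0/1 values.
BitStream = np.ndarray

PAIR_TO_BASE = {(0, 0): "A", (0, 1): "C", (1, 0): "G", (1, 1): "T"}
BASE_TO_PAIR = {b: p for p, b in PAIR_TO_BASE.items()}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def as_bits(bits) -> BitStream:
    """Coerce a sequence of 0/1 values to a bit array, validating symbols."""
    arr = np.asarray(bits, dtype=np.uint8)
    if arr.ndim != 1 and arr.size > 0:
        arr = arr.ravel()
    if arr.size and arr.max(initial=0) > 1:
        raise ValueError("bit stream may only contain 0 and 1")
    return arr


def bytes_to_bits(payload: bytes) -> BitStream:
    """Unpack bytes into bits, MSB first within each byte."""
    return np.unpackbits(np.frombuffer(bytes(payload), dtype=np.uint8))


def bits_to_bytes(bits: BitStream) -> bytes:
    """Pack a bit stream back into bytes (inverse of :func:`bytes_to_bits`).

    The length must be a multiple of 8.
    """
    arr = as_bits(bits)
    if arr.size % 8:
        raise ValueError(f"bit stream length {arr.size} is not a multiple of 8")
    return np.packbits(arr).tobytes()


def bits_to_dna(bits: BitStream, pad: bool = False) -> str:
    """Map bit pairs to nucleotides (00->A, 01->C, 10->G, 11->T).

    Parameters
    ----------
    bits:
        Bit stream of even length.  An odd-length stream is rejected unless
        ``pad`` is set, in which case a single 0 bit is appended first (the
        caller is responsible for recording the pad).
    """
    arr = as_bits(bits)
    if arr.size % 2:
        if not pad:
            raise ValueError(
                f"bit stream length {arr.size} is odd; pass pad=True to right-pad"
            )
        arr = np.concatenate([arr, np.zeros(1, dtype=np.uint8)])
    idx = arr[0::2] * 2 + arr[1::2]
    return _BASES[idx].tobytes().decode("ascii")


def dna_to_bits(seq: str) -> BitStream:
    """Map nucleotides back to bit pairs (exact inverse of :func:`bits_to_dna`)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    idx = np.full(raw.size, -1, dtype=np.int8)
    for base, code in zip(b"ACGT", range(4)):
        idx[raw == base] = code
    bad = np.nonzero(idx < 0)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(f"non-ACGT character {seq[pos]!r} at position {pos}")
    out = np.empty(2 * raw.size, dtype=np.uint8)
    out[0::2] = idx >> 1
    out[1::2] = idx & 1
    return out


@dataclass(frozen=True)
class StrandLayout:
    """Geometry of one coded DNA strand.

    ``strand_length_nt`` fixes the *coded* strand length (150 or 300 nt in
    the experiments), so the coded bit budget is ``2 * strand_length_nt``.
    For a rate k/n code the encoder consumes ``coded_bits * k / n`` input
    bits per strand, of which ``flush_bits`` are zero termination bits,
    leaving ``data_bits_per_strand`` payload bits.
    """

    strand_length_nt: int
    code_rate: Fraction  # k/n; Fraction(1, 1) means uncoded
    flush_bits: int = 0

    def __post_init__(self):
        if self.strand_length_nt <= 0:
            raise ValueError("strand_length_nt must be positive")
        if self.flush_bits < 0:
            raise ValueError("flush_bits must be non-negative")
        coded = self.coded_bits
        k, n = self.code_rate.numerator, self.code_rate.denominator
        if coded * k % n:
            raise ValueError(
                f"coded bit count {coded} is not divisible by n/k={n}/{k}"
            )
        if self.data_bits_per_strand <= 0:
            raise ValueError("layout leaves no payload bits per strand")

    @property
    def coded_bits(self) -> int:
        return 2 * self.strand_length_nt

    @property
    def input_bits_per_strand(self) -> int:
        """Encoder input bits per strand, termination included."""
        k, n = self.code_rate.numerator, self.code_rate.denominator
        return self.coded_bits * k // n

    @property
    def data_bits_per_strand(self) -> int:
        return self.input_bits_per_strand - self.flush_bits

    @classmethod
    def for_code(cls, strand_length_nt: int, code) -> "StrandLayout":
        """Layout for a :class:`~strandcode.codes.ConvolutionalCode`, or uncoded.

        ``code=None`` yields an uncoded layout where every coded bit is a
        payload bit.
        """
        if code is None:
            return cls(strand_length_nt, Fraction(1, 1), 0)
        flush_symbols = math.ceil(code.memory / code.k)
        return cls(
            strand_length_nt,
            Fraction(code.k, code.n),
            flush_symbols * code.k,
        )


def chunk_payload(bits: BitStream, layout: StrandLayout):
    """Split a bit stream into strand-sized chunks.

    Returns ``(chunks, pad_bits)`` where every chunk holds exactly
    ``layout.data_bits_per_strand`` bits, the final chunk is zero-padded,
    and ``pad_bits`` records how many pad bits were appended so that
    :func:`reassemble_chunks` is exact.
    """
    arr = as_bits(bits)
    size = layout.data_bits_per_strand
    n_chunks = max(1, math.ceil(arr.size / size))
    pad = n_chunks * size - arr.size
    padded = np.concatenate([arr, np.zeros(pad, dtype=np.uint8)])
    return [padded[i * size:(i + 1) * size] for i in range(n_chunks)], pad


def reassemble_chunks(chunks, pad_bits: int) -> BitStream:
    """Concatenate chunks and strip the recorded zero padding."""
    joined = np.concatenate([as_bits(c) for c in chunks]) if chunks else np.zeros(0, np.uint8)
    if pad_bits:
        joined = joined[:-pad_bits]
    return joined
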