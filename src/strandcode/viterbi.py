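"""Hard-decision Viterbi decoding of convolutionally coded bit streams.

The decoder runs dynamic programming over the code trellis with a Hamming
branch metric on n-bit output symbols and returns the input sequence whose
codeword is closest to the received stream.  Ties are resolved by a single
global rule: among minimum-metric inputs, prefer the sequence whose input
symbols, read from most recent to oldest, are lexicographically smallest.
That order is suffix-compatible (extending two tied survivors by the same
symbol preserves their order), so it decomposes over the trellis: each
survivor carries its reversed input-symbol sequence and tied extensions
are compared directly.  The exhaustive test oracle applies the identical
rule, which makes decoder/oracle agreement exact rather than modulo tie
luck.

States and symbols are packed into integers internally (first register
bit = most significant), so "lowest state index" and "lexicographically
smaller symbol" coincide with integer order.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .codes import ConvolutionalCode
from .payload import BitStream, StrandLayout, as_bits, dna_to_bits

__all__ = ["DecodeResult", "decode", "decode_strand"]


@dataclass(frozen=True)
class DecodeResult:
    """Best-effort decode of one received stream.

    ``path_metric`` is the total Hamming distance between the received
    stream and the codeword of ``decoded_bits``; it is 0 exactly when the
    received stream is itself a valid codeword.  The decoder never aborts:
    under corruption beyond the code's correction radius it still returns
    the closest codeword (``failed`` stays False; callers judge failure by
    comparing decoded output with ground truth).
    """

    decoded_bits: BitStream
    path_metric: int
    terminal_state: tuple
    failed: bool = False


@lru_cache(maxsize=None)
def _tables(code: ConvolutionalCode):
    """Integer transition tables: trans[state][input] = (next_state, output)."""
    m, k = code.memory, code.k
    table = []
    for s_idx in range(2 ** m):
        state = tuple((s_idx >> (m - 1 - i)) & 1 for i in range(m))
        row = []
        for b_idx in range(2 ** k):
            sym = tuple((b_idx >> (k - 1 - i)) & 1 for i in range(k))
            ns, out = code.step(state, sym)
            ns_idx = sum(bit << (m - 1 - i) for i, bit in enumerate(ns))
            out_idx = sum(bit << (code.n - 1 - i) for i, bit in enumerate(out))
            row.append((ns_idx, out_idx))
        table.append(tuple(row))
    return tuple(table)


def _unpack_state(idx: int, m: int) -> tuple:
    return tuple((idx >> (m - 1 - i)) & 1 for i in range(m))


def decode(code: ConvolutionalCode, received: BitStream, terminated: bool = True) -> DecodeResult:
    """Maximum-likelihood (minimum Hamming distance) decode over the trellis.

    With ``terminated`` the path must end in the all-zero state and the
    trailing flush symbols are stripped from the returned bits; otherwise
    the best metric over all terminal states wins (the recent-symbol tie
    rule, which for terminal states equals lowest state index).
    """
    rec = as_bits(received)
    n, k, m = code.n, code.k, code.memory
    if rec.size % n:
        raise ValueError(f"received length {rec.size} is not divisible by n={n}")
    steps = rec.size // n
    if steps == 0:
        return DecodeResult(np.zeros(0, np.uint8), 0, code.start_state)

    trans = _tables(code)
    n_states = 2 ** m
    # received symbols packed to ints, first bit most significant
    weights = 1 << np.arange(n - 1, -1, -1)
    rsyms = (rec.reshape(steps, n) * weights).sum(axis=1)

    popcount = [bin(x).count("1") for x in range(2 ** n)]
    # survivors[state] = (metric, reversed tuple of input-symbol ints) or None
    survivors = [None] * n_states
    survivors[0] = (0, ())
    flush_start = steps - code.flush_symbols if terminated else steps
    for t in range(steps):
        r = int(rsyms[t])
        # during the flush steps of a terminated stream only the all-zero
        # input symbol is admissible (the encoder appended zeros)
        n_inputs = 1 if t >= flush_start else 2 ** k
        nxt = [None] * n_states
        for s in range(n_states):
            surv = survivors[s]
            if surv is None:
                continue
            metric, rev = surv
            for b, (ns, out) in enumerate(trans[s][:n_inputs]):
                cand_metric = metric + popcount[out ^ r]
                cur = nxt[ns]
                if cur is None or cand_metric < cur[0]:
                    nxt[ns] = (cand_metric, (b,) + rev)
                elif cand_metric == cur[0]:
                    cand_rev = (b,) + rev
                    if cand_rev < cur[1]:
                        nxt[ns] = (cand_metric, cand_rev)
        survivors = nxt

    if terminated:
        best_state = 0
        if survivors[0] is None:  # fewer steps than needed to return to zero
            best_state = min(
                (s for s in range(n_states) if survivors[s] is not None),
                key=lambda s: (survivors[s], s),
            )
    else:
        best_state = min(
            (s for s in range(n_states) if survivors[s] is not None),
            key=lambda s: (survivors[s], s),
        )
    metric, rev = survivors[best_state]

    symbols = rev[::-1]
    if terminated:
        symbols = symbols[: max(0, len(symbols) - code.flush_symbols)]
    bits = np.asarray(
        [(b >> (k - 1 - i)) & 1 for b in symbols for i in range(k)], dtype=np.uint8
    )
    return DecodeResult(bits, int(metric), _unpack_state(best_state, m))


def decode_strand(code: ConvolutionalCode, strand: str, layout: StrandLayout) -> DecodeResult:
    """Decode one DNA strand back to its payload bits.

    Converts bases to bits, Viterbi-decodes with termination, and drops
    the flush bits, leaving ``layout.data_bits_per_strand`` payload bits.
    The strand must have exactly ``layout.strand_length_nt`` bases (the
    substitution-only channel preserves length; indel-corrupted strands
    are out of the decoder's scope).
    """
    if len(strand) != layout.strand_length_nt:
        raise ValueError(
            f"strand length {len(strand)} does not match layout "
            f"({layout.strand_length_nt} nt)"
        )
    bits = dna_to_bits(strand)[: layout.coded_bits]
    result = decode(code, bits, terminated=True)
    data = result.decoded_bits[: layout.data_bits_per_strand]
    return DecodeResult(data, result.path_metric, result.terminal_state, result.failed)
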