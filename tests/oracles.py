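"""Independent oracles used by the tests.

These deliberately re-derive results through different routes than the
production code: the table-walk encoder uses an explicit transition
dictionary instead of generator-tap arithmetic, and the brute-force
decoder enumerates every candidate input instead of running dynamic
programming over the trellis.
"""

from itertools import combinations, product

import numpy as np

from strandcode.codes import encode

# Full 16-edge transition table of the rate-1/3 code, written out literally
# from the shift-register rules (o1 = b^s3, o2 = s2^s3, o3 = s1^s3;
# next state = input bit prepended, oldest bit dropped).  The four
# transitions exercised by the canonical worked example are among these.
TABLE_13 = {
    ("000", 0): ("000", "000"), ("000", 1): ("100", "100"),
    ("001", 0): ("000", "111"), ("001", 1): ("100", "011"),
    ("010", 0): ("001", "010"), ("010", 1): ("101", "110"),
    ("011", 0): ("001", "101"), ("011", 1): ("101", "001"),
    ("100", 0): ("010", "001"), ("100", 1): ("110", "101"),
    ("101", 0): ("010", "110"), ("101", 1): ("110", "010"),
    ("110", 0): ("011", "011"), ("110", 1): ("111", "111"),
    ("111", 0): ("011", "100"), ("111", 1): ("111", "000"),
}


def table_walk_encode_13(bits):
    """Independent rate-1/3 encoder: literal table lookup, no tap arithmetic."""
    state = "000"
    out = []
    for b in bits:
        state, output = TABLE_13[(state, int(b))]
        out.extend(int(c) for c in output)
    return np.asarray(out, dtype=np.uint8)


def enumerate_inputs(code, n_symbols):
    """All input bit arrays of ``n_symbols`` symbols for a rate-k/n code."""
    for bits in product((0, 1), repeat=n_symbols * code.k):
        yield np.asarray(bits, dtype=np.uint8)


def symbols_of(code, bits):
    """Input bit array -> tuple of symbol ints (first bit most significant)."""
    k = code.k
    return tuple(
        int(sum(int(b) << (k - 1 - i) for i, b in enumerate(bits[j:j + k])))
        for j in range(0, len(bits), k)
    )


def brute_force_decode(code, received, terminated=True):
    """Exhaustive minimum-Hamming-distance decode.

    Enumerates every candidate input, encodes it, and picks the minimum
    distance codeword; ties are resolved by comparing input symbols from
    most recent to oldest (smaller first) -- the decoder's documented tie
    rule.  Returns ``(bits, metric)``.
    """
    received = np.asarray(received, dtype=np.uint8)
    steps = received.size // code.n
    n_data = steps - (code.flush_symbols if terminated else 0)
    best = None
    for bits in enumerate_inputs(code, n_data):
        coded = encode(code, bits, terminate=terminated).coded_bits
        metric = int((coded != received).sum())
        key = (metric, symbols_of(code, bits)[::-1])
        if best is None or key < best[0]:
            best = (key, bits)
    return best[1], best[0][0]


def corruption_patterns(n_bits, max_flips):
    """All 0/1 masks of ``n_bits`` with at most ``max_flips`` ones."""
    for w in range(max_flips + 1):
        for positions in combinations(range(n_bits), w):
            mask = np.zeros(n_bits, dtype=np.uint8)
            mask[list(positions)] = 1
            yield mask


def codebook(code, n_symbols, terminated=True):
    """(inputs, codewords) matrices for every input of ``n_symbols`` symbols."""
    inputs = np.array(
        list(product((0, 1), repeat=n_symbols * code.k)), dtype=np.uint8
    )
    words = np.array(
        [encode(code, row, terminate=terminated).coded_bits for row in inputs],
        dtype=np.uint8,
    )
    return inputs, words
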