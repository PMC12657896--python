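"""Feedforward convolutional encoders over shift-register finite state machines.

A rate-k/n code consumes k input bits per step and emits n output bits.
The encoder state is the content of an m-bit shift register; on input
symbol ``b`` the next state is ``b`` prepended to the state with the
oldest bits dropped.  Each output bit is a GF(2) inner product of a tap
vector with ``(input bits, state bits)``.

Three codes are registered, addressable as ``"1/3"``, ``"1/2"`` and
``"2/3"``.  The rate-1/3 taps are fixed by the four canonical worked-example
transitions (000 --1--> 100 / 100, 100 --0--> 010 / 001, 010 --1--> 101 / 110,
plus the all-zero self loop); the free tap on the oldest register bit was
set on each output to maximise the code's free distance (6).  The 1/2 code
uses the standard constraint-length-4 generators 15/17 (octal, free
distance 6); the 2/3 code shifts two bits per step through the same 3-bit
register with taps chosen by exhaustive search for maximal free distance
among 8-state rate-2/3 feedforward codes (4).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .payload import BitStream, as_bits

__all__ = ["ConvolutionalCode", "EncodedStrand", "build_code", "SUPPORTED_RATES"]

State = tuple  # m-tuple of 0/1
Symbol = tuple  # k-tuple (input) or n-tuple (output) of 0/1


@dataclass(frozen=True)
class ConvolutionalCode:
    """Finite-state-machine description of a feedforward rate-k/n code."""

    name: str
    k: int
    n: int
    memory: int
    #: n tap vectors, each of length k + memory, ordered (input bits, state bits).
    taps: tuple
    generator_spec: str = field(default="", compare=False)

    def __post_init__(self):
        if len(self.taps) != self.n:
            raise ValueError("need one tap vector per output bit")
        for g in self.taps:
            if len(g) != self.k + self.memory:
                raise ValueError("tap vector length must be k + memory")

    @property
    def start_state(self) -> State:
        return (0,) * self.memory

    @property
    def states(self):
        """All 2^m register contents, in lexicographic order."""
        return list(product((0, 1), repeat=self.memory))

    @property
    def flush_symbols(self) -> int:
        """Zero input symbols needed to return any state to all-zero."""
        return -(-self.memory // self.k)

    def input_symbols(self):
        return list(product((0, 1), repeat=self.k))

    def step(self, state: State, input_symbol: Symbol):
        """One encoder transition: ``(state, input) -> (next_state, output)``."""
        if len(state) != self.memory or any(b not in (0, 1) for b in state):
            raise ValueError(f"malformed state {state!r} for memory {self.memory}")
        if len(input_symbol) != self.k or any(b not in (0, 1) for b in input_symbol):
            raise ValueError(f"input symbol {input_symbol!r} must be {self.k} bits")
        vec = tuple(input_symbol) + tuple(state)
        output = tuple(
            sum(g_i & v_i for g_i, v_i in zip(g, vec)) & 1 for g in self.taps
        )
        next_state = vec[: self.memory]
        return next_state, output

    def transitions(self):
        """The full transition map as ``{(state, input): (next_state, output)}``."""
        return {
            (s, b): self.step(s, b)
            for s in self.states
            for b in self.input_symbols()
        }

    def dump_tsv(self) -> str:
        """Tab-separated state-machine dump for inspection."""
        buf = io.StringIO()
        buf.write("state\tinput\tnext_state\toutput\n")
        for (s, b), (ns, out) in self.transitions().items():
            row = ("".join(map(str, t)) for t in (s, b, ns, out))
            buf.write("\t".join(row) + "\n")
        return buf.getvalue()


@dataclass(frozen=True)
class EncodedStrand:
    """Result of encoding one input stream."""

    input_bits: BitStream
    coded_bits: BitStream
    terminated: bool
    final_state: State

    def __post_init__(self):
        object.__setattr__(self, "input_bits", as_bits(self.input_bits))
        object.__setattr__(self, "coded_bits", as_bits(self.coded_bits))


_REGISTRY = {
    # Worked-example code: output1 = b + s3, output2 = s2 + s3, output3 = s1 + s3.
    "1/3": ConvolutionalCode(
        name="1/3",
        k=1,
        n=3,
        memory=3,
        taps=((1, 0, 0, 1), (0, 0, 1, 1), (0, 1, 0, 1)),
        generator_spec=(
            "o1 = b ^ s3; o2 = s2 ^ s3; o3 = s1 ^ s3 over register (s1,s2,s3); "
            "free distance 6"
        ),
    ),
    "1/2": ConvolutionalCode(
        name="1/2",
        k=1,
        n=2,
        memory=3,
        taps=((1, 1, 0, 1), (1, 1, 1, 1)),
        generator_spec="generators 15/17 octal (constraint length 4); free distance 6",
    ),
    "2/3": ConvolutionalCode(
        name="2/3",
        k=2,
        n=3,
        memory=3,
        taps=((1, 0, 1, 0, 1), (0, 1, 0, 1, 1), (1, 1, 1, 1, 0)),
        generator_spec=(
            "two input bits shifted per step through a 3-bit register; taps "
            "chosen by exhaustive search over 8-state feedforward codes; "
            "free distance 4"
        ),
    ),
}

SUPPORTED_RATES = tuple(_REGISTRY)


def build_code(rate_id: str) -> ConvolutionalCode:
    """Look up a registered code by its rate string (``1/3``, ``1/2`` or ``2/3``)."""
    try:
        return _REGISTRY[rate_id]
    except KeyError:
        raise ValueError(
            f"unknown code rate {rate_id!r}; supported rates: {', '.join(_REGISTRY)}"
        ) from None


def encode(code: ConvolutionalCode, bits: BitStream, terminate: bool = True) -> EncodedStrand:
    """Encode a bit stream by walking the finite state machine from all-zero.

    With ``terminate`` the input is extended with ``ceil(m/k)`` all-zero
    flush symbols so the encoder ends in the all-zero state, which anchors
    Viterbi traceback.
    """
    arr = as_bits(bits)
    if arr.size % code.k:
        raise ValueError(
            f"input length {arr.size} is not divisible by k={code.k}"
        )
    symbols = [tuple(int(b) for b in arr[i:i + code.k]) for i in range(0, arr.size, code.k)]
    if terminate:
        symbols += [(0,) * code.k] * code.flush_symbols
    state = code.start_state
    out = []
    for sym in symbols:
        state, output = code.step(state, sym)
        out.extend(output)
    full_input = np.asarray([b for sym in symbols for b in sym], dtype=np.uint8)
    return EncodedStrand(
        input_bits=full_input,
        coded_bits=np.asarray(out, dtype=np.uint8),
        terminated=terminate,
        final_state=state,
    )
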