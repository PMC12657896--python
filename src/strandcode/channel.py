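"""Error injection into nucleotide sequences under a characterized profile.

The channel emulates the residual error behaviour of a (possibly
compressed) nanopore basecaller as independent per-base events: walking
the clean sequence left to right, each position suffers at most one of
insertion (a uniform random base emitted *before* the current base),
deletion, or substitution (uniform over the three other bases).  A single
uniform draw per position with stacked thresholds makes the three events
mutually exclusive while keeping each type's marginal probability exactly
its configured rate.  An optional piecewise-linear positional density over
normalized position [0, 1] redistributes (without rescaling) each rate
along the strand, mimicking the end-loaded deletion pattern seen in real
nanopore reads.

Every corruption is recorded in a replayable log, so ground truth for the
alignment-based error metrics is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PositionalWeight",
    "ChannelProfile",
    "CorruptionEvent",
    "apply_substitutions",
    "apply_channel",
    "replay_log",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PositionalWeight:
    """Piecewise-linear density over normalized position in [0, 1].

    ``xs`` are breakpoints (ascending, spanning [0, 1]) and ``ys`` the
    non-negative density values at them.  On construction the density is
    normalized to integrate to 1, so it redistributes a mean rate along
    the sequence without changing it.
    """

    xs: tuple
    ys: tuple

    def __post_init__(self):
        xs = np.asarray(self.xs, dtype=float)
        ys = np.asarray(self.ys, dtype=float)
        if xs.size < 2 or xs.size != ys.size:
            raise ValueError("need matching xs/ys with at least two breakpoints")
        if xs[0] != 0.0 or xs[-1] != 1.0 or np.any(np.diff(xs) < 0):
            raise ValueError("xs must run from 0 to 1 without decreasing")
        if np.any(ys < 0):
            raise ValueError("density values must be non-negative")
        area = np.trapezoid(ys, xs)
        if area <= 0:
            raise ValueError("density must have positive mass")
        object.__setattr__(self, "xs", tuple(xs))
        object.__setattr__(self, "ys", tuple(ys / area))

    def __call__(self, pos: np.ndarray) -> np.ndarray:
        return np.interp(pos, self.xs, self.ys)


def end_loaded_weight(end_fraction: float = 0.05, end_share: float = 0.9) -> PositionalWeight:
    """Density putting ``end_share`` of the mass in the first/last ``end_fraction``."""
    e = end_fraction
    hi = end_share / (2 * e)
    lo = (1 - end_share) / (1 - 2 * e)
    return PositionalWeight((0.0, e, e, 1 - e, 1 - e, 1.0), (hi, hi, lo, lo, hi, hi))


def _parse_rate(value) -> float:
    """Accept a fraction, or a percent string with explicit ``%`` suffix."""
    if isinstance(value, str):
        if not value.endswith("%"):
            raise ValueError(f"string rate {value!r} must carry a '%' suffix")
        return float(value[:-1]) / 100.0
    return float(value)


@dataclass(frozen=True)
class ChannelProfile:
    """Per-base substitution/insertion/deletion probabilities plus weighting."""

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    positional_weight: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = _parse_rate(getattr(self, name))
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name}={r} outside [0, 1]")
            object.__setattr__(self, name, r)
        if self.ins_rate + self.del_rate + self.sub_rate > 1.0:
            raise ValueError("summed per-position event probability exceeds 1")
        weights = {}
        for kind, w in dict(self.positional_weight).items():
            if kind not in ("sub", "ins", "del"):
                raise ValueError(f"unknown positional weight target {kind!r}")
            weights[kind] = w if isinstance(w, PositionalWeight) else PositionalWeight(**w)
        object.__setattr__(self, "positional_weight", weights)

    def weight_for(self, kind: str):
        return self.positional_weight.get(kind)

    def to_json(self) -> str:
        payload = {
            "sub_rate": self.sub_rate,
            "ins_rate": self.ins_rate,
            "del_rate": self.del_rate,
            "positional_weight": {
                k: {"xs": list(w.xs), "ys": list(w.ys)}
                for k, w in self.positional_weight.items()
            },
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ChannelProfile":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class CorruptionEvent:
    """One channel event; ``ref_pos`` indexes the clean sequence.

    Insertions emit ``emitted`` before the base at ``ref_pos``; deletions
    drop the base; substitutions replace ``original`` with ``emitted``.
    """

    kind: str  # "ins" | "del" | "sub"
    ref_pos: int
    original: str
    emitted: str


def _seq_to_idx(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    idx = np.full(raw.size, -1, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        idx[raw == ord(base)] = code
    if np.any(idx < 0):
        pos = int(np.nonzero(idx < 0)[0][0])
        raise ValueError(f"non-ACGT character {seq[pos]!r} at position {pos}")
    return idx


def _scaled(rate: float, weight, pos: np.ndarray) -> np.ndarray:
    if weight is None:
        return np.full(pos.size, rate)
    scaled = rate * weight(pos)
    if np.any(scaled > 1.0):
        raise ValueError("positional weighting pushes a rate above 1")
    return scaled


def apply_substitutions(seq: str, rate: float, rng) -> tuple[str, list]:
    """Substitute each base independently with probability ``rate``.

    Replacements are uniform over the three other bases; output length
    equals input length.  ``rng`` is a seed or ``numpy.random.Generator``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"substitution rate {rate} outside [0, 1]")
    rng = np.random.default_rng(rng)
    idx = _seq_to_idx(seq)
    hit = rng.random(idx.size) < rate
    # offset 1..3 from the original base, mod 4, never the identity
    offsets = rng.integers(1, 4, size=idx.size)
    new_idx = idx.copy()
    new_idx[hit] = (idx[hit] + offsets[hit]) % 4
    out = _BASES[new_idx].tobytes().decode("ascii")
    log = [
        CorruptionEvent("sub", int(i), seq[i], out[i])
        for i in np.nonzero(hit)[0]
    ]
    return out, log


def apply_channel(seq: str, profile: ChannelProfile, rng=None) -> tuple[str, list]:
    """Run the full insertion/deletion/substitution channel over a sequence.

    One uniform draw per reference position selects at most one event:
    insertion is tested first, then deletion, then substitution, each at
    its (positionally weighted) rate.  Returns the corrupted sequence and
    the replayable event log.
    """
    if rng is None:
        rng = profile.seed
    rng = np.random.default_rng(rng)
    idx = _seq_to_idx(seq)
    L = idx.size
    if L == 0:
        return "", []
    pos = np.arange(L) / L
    p_ins = _scaled(profile.ins_rate, profile.weight_for("ins"), pos)
    p_del = _scaled(profile.del_rate, profile.weight_for("del"), pos)
    p_sub = _scaled(profile.sub_rate, profile.weight_for("sub"), pos)
    u = rng.random(L)
    ins_hit = u < p_ins
    del_hit = (~ins_hit) & (u < p_ins + p_del)
    sub_hit = (~ins_hit) & (~del_hit) & (u < p_ins + p_del + p_sub)
    ins_bases = rng.integers(0, 4, size=L)
    sub_offsets = rng.integers(1, 4, size=L)

    out_idx = []
    log = []
    for i in range(L):
        if ins_hit[i]:
            b = int(ins_bases[i])
            out_idx.append(b)
            log.append(CorruptionEvent("ins", i, seq[i], "ACGT"[b]))
            out_idx.append(idx[i])
        elif del_hit[i]:
            log.append(CorruptionEvent("del", i, seq[i], "-"))
        elif sub_hit[i]:
            b = (idx[i] + int(sub_offsets[i])) % 4
            out_idx.append(b)
            log.append(CorruptionEvent("sub", i, seq[i], "ACGT"[b]))
        else:
            out_idx.append(idx[i])
    out = _BASES[np.asarray(out_idx, dtype=np.int8)].tobytes().decode("ascii")
    return out, log


def replay_log(seq: str, log: list) -> str:
    """Re-apply a corruption log to the clean sequence (exact reproduction)."""
    events = {}
    for ev in log:
        events.setdefault(ev.ref_pos, []).append(ev)
    out = []
    for i, base in enumerate(seq):
        here = events.get(i, [])
        consumed = False
        for ev in here:
            if ev.kind == "ins":
                out.append(ev.emitted)
            elif ev.kind == "del":
                consumed = True
            elif ev.kind == "sub":
                out.append(ev.emitted)
                consumed = True
        if not consumed:
            out.append(base)
    return "".join(out)
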