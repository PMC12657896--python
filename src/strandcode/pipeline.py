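"""End-to-end encode -> corrupt -> decode -> measure experiment runners.

The simulation workflow mirrors a base-level read channel for data-carrying
DNA: a byte payload is unpacked to bits, chunked to strand-sized payloads,
convolutionally encoded (optional), mapped two bits per base to nucleotide
strands, pushed through a substitution channel, Viterbi-decoded (optional),
mapped back, and compared strand by strand against the original data-DNA
with Smith-Waterman alignment.  Error rates are DNA-level fractions; the
uncoded baseline runs the identical pipeline without encoder and decoder.

Reported quantities are kept as fractions internally; rendering to percent
happens only in tables and the CLI.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .align import DEFAULT_SCORING, Scoring, dna_error_rate
from .channel import ChannelProfile, apply_channel, apply_substitutions
from .codes import build_code, encode
from .payload import (
    StrandLayout,
    bits_to_dna,
    bytes_to_bits,
    chunk_payload,
)
from .viterbi import decode_strand

__all__ = [
    "ExperimentConfig",
    "TradeoffResult",
    "load_text_fixture",
    "encode_payload_to_strands",
    "run_correction_experiment",
    "calibrate_channel",
    "run_compensation_experiment",
    "generate_fixtures",
    "improvement",
]

FIXTURE_BYTES = 8192


def load_text_fixture() -> bytes:
    """The bundled 8,192-byte public-domain text excerpt used as sample data."""
    data = (
        importlib.resources.files("strandcode.data")
        .joinpath("sample_text_8k.txt")
        .read_bytes()
    )
    assert len(data) == FIXTURE_BYTES
    return data


@dataclass(frozen=True)
class ExperimentConfig:
    """One simulation condition; a config plus seeds fixes all outputs."""

    strand_length_nt: int = 300
    code_rate: str = "none"  # "none", "1/3", "1/2" or "2/3"
    sub_rate: float = 0.0
    seeds: tuple = tuple(range(10))
    payload: bytes | None = None  # None -> bundled text fixture
    scoring: Scoring = DEFAULT_SCORING

    def __post_init__(self):
        if self.code_rate not in ("none", "1/3", "1/2", "2/3"):
            raise ValueError(f"unknown code rate {self.code_rate!r}")
        if not 0.0 <= self.sub_rate <= 1.0:
            raise ValueError("sub_rate outside [0, 1]")
        if not self.seeds:
            raise ValueError("at least one seed is required")
        if self.strand_length_nt <= 0:
            raise ValueError("strand_length_nt must be positive")

    @property
    def code(self):
        return None if self.code_rate == "none" else build_code(self.code_rate)

    @property
    def layout(self) -> StrandLayout:
        return StrandLayout.for_code(self.strand_length_nt, self.code)

    def payload_bytes(self) -> bytes:
        return self.payload if self.payload is not None else load_text_fixture()


@dataclass(frozen=True)
class TradeoffResult:
    """Measured error statistics for one experiment condition."""

    config: ExperimentConfig
    mean_error_rate: float          # fraction, averaged over strands and seeds
    per_seed_means: tuple
    per_strand_rates: tuple         # pooled across seeds
    frac_error_free: float
    mean_path_metric: float | None  # None for uncoded runs

    @property
    def n_strands(self) -> int:
        return len(self.per_strand_rates) // len(self.per_seed_means)


def improvement(baseline: float, coded: float):
    """Relative error-rate improvement ``(baseline - coded) / baseline``.

    Undefined (None) when the baseline is zero.
    """
    if baseline == 0:
        return None
    return (baseline - coded) / baseline


def encode_payload_to_strands(payload: bytes, strand_length_nt: int, code):
    """Encode a payload into fixed-length DNA strands.

    Returns ``(strands, refs, pad_bits)`` where ``strands`` are the coded
    nucleotide sequences written to the channel and ``refs`` are the
    data-DNA renderings of each chunk (the comparison frame for error
    measurement).  For an uncoded run (``code=None``) the two coincide.
    """
    layout = StrandLayout.for_code(strand_length_nt, code)
    chunks, pad_bits = chunk_payload(bytes_to_bits(payload), layout)
    strands, refs = [], []
    for chunk in chunks:
        ref = bits_to_dna(chunk, pad=True)
        if code is None:
            strand = ref
        else:
            coded = encode(code, chunk, terminate=True).coded_bits
            strand = bits_to_dna(coded, pad=True)
        assert len(strand) == strand_length_nt
        strands.append(strand)
        refs.append(ref)
    return strands, refs, pad_bits


def run_correction_experiment(config: ExperimentConfig) -> TradeoffResult:
    """Run the full simulation workflow for one condition.

    Every seed corrupts every strand independently; the reported error
    rate is the mean DNA-level error over all (strand, seed) pairs, with
    reference bases left uncovered by the local alignment counted as
    errors so decode failures are not understated.
    """
    code = config.code
    layout = config.layout
    strands, refs, _ = encode_payload_to_strands(
        config.payload_bytes(), config.strand_length_nt, code
    )
    per_seed = []
    all_rates = []
    metrics = []
    error_free = 0
    for seed in config.seeds:
        rng = np.random.default_rng(seed)
        seed_rates = []
        for strand, ref in zip(strands, refs):
            corrupted, _ = apply_substitutions(strand, config.sub_rate, rng)
            if code is None:
                readback = corrupted
            else:
                result = decode_strand(code, corrupted, layout)
                metrics.append(result.path_metric)
                readback = bits_to_dna(result.decoded_bits, pad=True)
            rate = dna_error_rate(ref, readback, config.scoring)
            seed_rates.append(rate)
            if rate == 0:
                error_free += 1
        per_seed.append(float(np.mean(seed_rates)))
        all_rates.extend(seed_rates)
    return TradeoffResult(
        config=config,
        mean_error_rate=float(np.mean(all_rates)),
        per_seed_means=tuple(per_seed),
        per_strand_rates=tuple(all_rates),
        frac_error_free=error_free / len(all_rates),
        mean_path_metric=float(np.mean(metrics)) if metrics else None,
    )


def calibrate_channel(
    target_uncoded_rate: float,
    strand_length_nt: int = 300,
    payload: bytes | None = None,
    seeds: tuple = (0, 1, 2),
    rel_tol: float = 0.05,
    max_iter: int = 8,
):
    """Find the substitution probability whose *measured* uncoded error rate
    matches a target.

    The measured rate tracks the injected probability almost exactly (the
    substitution channel preserves length, so the alignment recovers nearly
    every event); a proportional fixed-point update therefore converges in
    a couple of iterations.  Returns ``(probability, achieved_rate)``.
    """
    if target_uncoded_rate == 0:
        return 0.0, 0.0
    if not 0.0 < target_uncoded_rate < 0.7:
        raise ValueError("target uncoded error rate must lie in (0, 0.7)")
    prob = target_uncoded_rate
    achieved = None
    for _ in range(max_iter):
        cfg = ExperimentConfig(
            strand_length_nt=strand_length_nt,
            code_rate="none",
            sub_rate=prob,
            seeds=tuple(seeds),
            payload=payload,
        )
        achieved = run_correction_experiment(cfg).mean_error_rate
        if achieved > 0 and abs(achieved - target_uncoded_rate) <= rel_tol * target_uncoded_rate:
            return prob, achieved
        if achieved == 0:
            prob = min(2 * prob, 0.75)
            continue
        prob = min(prob * target_uncoded_rate / achieved, 0.75)
    raise RuntimeError(
        f"calibration did not reach target {target_uncoded_rate} "
        f"(last achieved {achieved})"
    )


def run_compensation_experiment(profiles, codes, base_config: ExperimentConfig) -> pd.DataFrame:
    """Error-correction table for channels standing in for compressed basecallers.

    ``profiles`` is a list of ``(label, uncoded_error_rate)`` pairs; each
    channel's substitution probability is calibrated so its measured
    uncoded error matches the given rate, then every code in ``codes`` is
    run under that channel.  Returns a tidy table with uncoded and coded
    error rates (percent) and the improvement recomputed from its own cells.
    """
    if not profiles:
        raise ValueError("need at least one channel profile")
    rows = []
    for label, uncoded_target in profiles:
        prob, achieved = calibrate_channel(
            uncoded_target,
            strand_length_nt=base_config.strand_length_nt,
            payload=base_config.payload,
            seeds=base_config.seeds[:3] or base_config.seeds,
        )
        row = {
            "model": label,
            "uncoded_error_pct": 100 * achieved,
            "sub_probability": prob,
        }
        for code_rate in codes:
            res = run_correction_experiment(
                replace(base_config, code_rate=code_rate, sub_rate=prob)
            )
            imp = improvement(achieved, res.mean_error_rate)
            row[f"coded_{code_rate}_error_pct"] = 100 * res.mean_error_rate
            row[f"improvement_{code_rate}_pct"] = (
                100 * imp if imp is not None else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def generate_fixtures(kind: str, outdir, seed: int = 0, **params):
    """Write synthetic inputs for the pipeline and characterization tests.

    ``text``: the bundled 8,192-byte excerpt as a raw payload file.
    ``random``: ``n_bytes`` of seeded random payload.
    ``corrupted-read-set``: ``n_reads`` random references of ``read_length``
    bases plus reads drawn through a channel ``profile`` (reference FASTA,
    reads FASTA and a replayable corruption-log JSON).
    """
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if kind == "text":
        path = outdir / "sample_text.bin"
        path.write_bytes(load_text_fixture())
        return [path]
    if kind == "random":
        n = int(params.get("n_bytes", FIXTURE_BYTES))
        path = outdir / "random_payload.bin"
        path.write_bytes(rng.integers(0, 256, size=n, dtype=np.uint8).tobytes())
        return [path]
    if kind == "corrupted-read-set":
        n_reads = int(params.get("n_reads", 200))
        read_length = int(params.get("read_length", 1000))
        profile = params.get("profile") or ChannelProfile(
            sub_rate=0.01736, ins_rate=0.00698, del_rate=0.02240
        )
        refs, reads, logs = [], [], []
        for i in range(n_reads):
            ref = "".join(
                "ACGT"[b] for b in rng.integers(0, 4, size=read_length)
            )
            read, log = apply_channel(ref, profile, rng)
            refs.append((f"ref_{i}", ref))
            reads.append((f"read_{i}", read))
            logs.append(
                [{"kind": e.kind, "ref_pos": e.ref_pos, "original": e.original,
                  "emitted": e.emitted} for e in log]
            )
        ref_path = outdir / "references.fasta"
        read_path = outdir / "reads.fasta"
        log_path = outdir / "corruption_log.json"
        for path, records in ((ref_path, refs), (read_path, reads)):
            with open(path, "w") as fh:
                for name, seq in records:
                    fh.write(f">{name}\n{seq}\n")
        log_path.write_text(json.dumps(logs))
        return [ref_path, read_path, log_path]
    raise ValueError(f"unknown fixture kind {kind!r}")
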