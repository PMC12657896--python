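# strandcode

Convolutional error correction, channel simulation and alignment-based
error metrics for **data-carrying DNA**.

When binary data is stored in synthetic DNA, reading it back goes through
sequencing and a neural basecaller, and the read channel injects
insertions, deletions and substitutions. Because the writer controls the
data, simple per-strand error-correcting codes can absorb much of that
noise — including the *extra* noise introduced when the basecaller is
aggressively compressed by magnitude pruning. `strandcode` provides the
pieces needed to study that trade-off at the nucleotide level, with no
sequencer, GPU or external dataset:

- **Payload mapping** — bytes ↔ bits (MSB-first) ↔ nucleotides
  (`00→A, 01→C, 10→G, 11→T`), and chunking onto fixed-length strands
  (150 or 300 nt coded length).
- **Convolutional codes** — shift-register finite-state-machine encoders at
  rates 1/3, 1/2 and 2/3 (memory 3). A rate-*k/n* code emits *n* coded bits
  per *k* input bits; strands are terminated with zero flush bits so the
  encoder ends in the all-zero state.
- **Viterbi decoding** — exact maximum-likelihood hard-decision decoding
  over the code trellis with a Hamming branch metric and a deterministic
  tie rule, verified against brute-force enumeration.
- **DNA channel** — per-base substitution/insertion/deletion injection with
  optional positional weighting (end-loaded deletions, as seen in nanopore
  reads) and a fully replayable corruption log.
- **Error metrics** — Smith–Waterman local alignment (match +2,
  mismatch −1, gap −2), per-type error classification, rates normalized by
  reference length, end-trimming summaries and positional histograms.
- **Pruning mathematics** — one-shot and iterative global magnitude
  pruning, structured column pruning by L1 norm, the
  `(1 − 0.5ⁿ) × 100 %` sparsity schedule, and LSTM/linear parameter-count
  arithmetic, over abstract named weight matrices.
- **Experiment pipeline** — end-to-end runners that encode a payload,
  corrupt it, decode it, and measure the mean DNA-level error rate per
  condition, plus channel calibration to a target uncoded error rate.

## Worked example

Encode the 4-bit string `0,1,0,1` with the rate-1/3 encoder, then run the
bundled 8 KiB text payload through the full pipeline at a channel
calibrated to 1.5 % uncoded error on 300 nt strands:

```python
from strandcode import (ExperimentConfig, run_correction_experiment,
                        calibrate_channel, improvement, build_code, encode)

enc = encode(build_code("1/3"), [0, 1, 0, 1], terminate=False)
print("coded:", "".join(map(str, enc.coded_bits)), "final state:", enc.final_state)

prob, baseline = calibrate_channel(0.015, strand_length_nt=300, seeds=(0, 1, 2))
print(f"substitution probability {prob:.4f} -> uncoded error {100*baseline:.3f}%")
for rate in ("1/3", "1/2", "2/3"):
    res = run_correction_experiment(ExperimentConfig(
        strand_length_nt=300, code_rate=rate, sub_rate=prob, seeds=(0, 1, 2)))
    imp = improvement(baseline, res.mean_error_rate)
    print(f"rate {rate}: decoded error {100*res.mean_error_rate:.4f}%  "
          f"improvement {100*imp:+.1f}%  error-free strands {100*res.frac_error_free:.1f}%")
```

Output:

```
coded: 000100001110 final state: (1, 0, 1)
substitution probability 0.0150 -> uncoded error 1.500%
rate 1/3: decoded error 0.0536%  improvement +96.4%  error-free strands 98.1%
rate 1/2: decoded error 0.0982%  improvement +93.5%  error-free strands 91.9%
rate 2/3: decoded error 27.5182%  improvement -1734.5%  error-free strands 11.0%
```

The stronger codes (1/3, 1/2) cut the DNA-level error rate by well over an
order of magnitude and leave most strands error-free; the weak 2/3 code is
past its correction capability at this noise level, so decoder failures
*amplify* the error — the central trade-off the package exists to measure.

The same workflow is available from the shell:

```sh
strandcode encode payload.bin strands.fasta --code 1/3 --strand-length 300
strandcode corrupt strands.fasta noisy.fasta --sub-rate 0.015 --seed 7
strandcode decode noisy.fasta restored.bin --code 1/3 --strand-length 300
strandcode characterize refs.fasta reads.fasta --trim 0 --trim 10 --trim 30
strandcode sweep --sub-rate 0.015 --seeds 10
strandcode prune-plan --iterations 8 --fraction 0.5
```

## Layout

```
src/strandcode/
  payload.py    bits/bytes/DNA mapping, strand layout, chunking
  codes.py      convolutional encoder FSMs (1/3, 1/2, 2/3)
  viterbi.py    trellis decoder
  channel.py    error injection and corruption logs
  align.py      Smith-Waterman metrics and error classification
  pruning.py    magnitude-pruning schedules and parameter counts
  pipeline.py   end-to-end experiment runners and calibration
  cli.py        `strandcode` command-line interface
docs/methods.md   model, assumptions, parameter choices, limitations
```
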