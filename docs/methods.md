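# Methods

## The channel model

`strandcode` models the read-back path of a DNA storage system at the
*base* level: a clean nucleotide strand is transformed into a noisy one by
independent per-position events. Walking the strand left to right, each
position suffers at most one of

- **insertion** (probability `ins_rate`): a uniform random base is emitted
  before the current base;
- **deletion** (`del_rate`): the base is dropped;
- **substitution** (`sub_rate`): the base is replaced by one of the three
  other bases, uniformly.

A single uniform draw per position with stacked thresholds (insertion
tested first, then deletion, then substitution) makes the events mutually
exclusive while keeping each type's marginal probability exactly its
configured rate; this keeps the corruption log replayable and the
configured rates directly recoverable by alignment. An optional
piecewise-linear density over normalized position redistributes a rate
along the strand without changing its mean — the mechanism used to emulate
the end-loaded deletion pattern of real nanopore reads. The density is
normalized to integrate to 1 on construction.

What the model deliberately omits: signal-level ("squiggle") effects,
context-dependent error hotspots (homopolymers), PCR/synthesis bias,
strand dropout and copy counts, and correlated error bursts. Passing tests
therefore demonstrate the behaviour of the codes and metrics under an
idealized independent-events channel with realistic *rates*, not under
real sequencer physics. The error-correction experiments use the
substitution-only channel (length-preserving), because the per-strand
convolutional decoder has no insertion/deletion tolerance; indels are
exercised by the characterization metrics instead.

Default per-type rates for characterization fixtures are 0.698 %
insertions, 2.240 % deletions, 1.736 % substitutions per reference base —
typical mean rates for nanopore basecalling output.

## Codes

All three registered codes are feedforward shift-register machines with a
3-bit memory: the state is the last three input bits (newest first) and
each output bit is a GF(2) inner product of a tap vector with
`(input bits, state bits)`.

- **rate 1/3** (`o1 = b⊕s3, o2 = s2⊕s3, o3 = s1⊕s3`): the input/s1/s2 taps
  are fixed by the four canonical worked-example transitions
  (`000→100/100`, `100→010/001`, `010→101/110`, plus the zero self-loop);
  the remaining s3 taps were chosen by exhaustive search over the eight
  possibilities to maximize free distance. The result has free distance 6
  (two-error correction per constraint span). A structural consequence of
  the pinned transitions is that only the first output bit sees the
  current input; unterminated streams therefore lose distance on the final
  symbol, which is why strand encoding always terminates.
- **rate 1/2**: the standard constraint-length-4 pair 15/17 (octal), free
  distance 6.
- **rate 2/3**: two input bits shift through the same 3-bit register per
  step; taps chosen by exhaustive search over all 8-state feedforward
  (k=2, m=3) codes, reaching the maximal free distance 4 for this state
  count. It is intentionally the weakest code: the experiments use it to
  demonstrate the decoder-failure regime where coding *increases* the
  error rate.

Termination appends `ceil(m/k)` all-zero flush symbols (3 bits for the
k=1 codes, 2 symbols/4 bits for the 2/3 code) so every strand's path ends
in the all-zero state.

## Decoding

Hard-decision Viterbi over the code trellis with a Hamming branch metric
on n-bit output symbols. Soft information (basecaller probabilities) is
out of scope. Numerical/determinism choices:

- **Tie rule.** Among minimum-metric inputs the decoder returns the
  sequence whose input symbols, read most-recent-first, are
  lexicographically smallest. This order is suffix-compatible, so it
  decomposes over the trellis: each survivor carries its reversed symbol
  sequence and tied extensions are compared directly. The brute-force test
  oracle applies the identical order, making decoder/oracle agreement
  exact, not tie-lucky. For unterminated decoding the rule subsumes
  "lowest terminal state index" because the state register holds the most
  recent input bits.
- **Flush constraint.** In terminated mode the final `ceil(m/k)` trellis
  steps admit only the all-zero input symbol; without this the k=2 trellis
  contains terminal paths the encoder cannot emit.
- The decoder never aborts: beyond the correction radius it still returns
  the nearest codeword, and failure shows up in the measured error rate.

## Error measurement

Errors are measured on nucleotides, not bits (one base substitution is one
or two bit flips — 2 flips in 4 of the 12 ordered base pairs — so
bit-level rates would be ambiguous). The decoded strand's data-DNA is
aligned to the original data-DNA with Smith–Waterman (local, match +2,
mismatch −1, linear gap −2; Biopython's `PairwiseAligner` engine, with its
deterministic co-optimal tie order). Alignment columns classify as
insertion (gap in reference), deletion (gap in query) or substitution;
rates divide by reference length and positions are normalized by it.

Two deliberate choices:

- **Uncovered flanks count as errors** in the pipeline metric. A
  catastrophically mis-decoded strand can still contain a short
  high-identity local match; counting only within-alignment errors would
  understate the damage. (`dna_error_rate(..., count_uncovered=False)`
  gives the within-alignment variant.)
- **Terminal-edit ambiguity is accepted.** Local alignment can clip an
  edit at the extreme ends of a sequence (a terminal mismatch or gap never
  improves a local score), and adjacent edits can merge (insertion +
  deletion ↔ substitution). Exact log recovery is therefore only asserted
  for well-separated, non-terminal edits; aggregate rates are compared
  within binomial sampling bands.

End-trimming (`trimmed_error_rates`) keeps only errors whose reference
position lies in `[K, L−K)` and shrinks the denominator accordingly.
Monotone decline of the total rate in K holds when the error mass is
concentrated in a zone wider than the largest K — the configuration the
tests construct; it is not a theorem for arbitrary channels, since the
denominator shrinks too.

## Pipeline and calibration

One experiment condition = (payload, strand length, code, substitution
probability, seeds). The payload is unpacked to bits, chunked to
`data_bits_per_strand = 2·nt·k/n − flush_bits` per strand (197 bits for
rate 1/3 at 300 nt), encoded, mapped to DNA, corrupted once per seed, and
decoded; the reported number is the mean DNA-level error over all
(strand, seed) pairs. A strand whose data-bit count is odd gets a single
recorded zero pad bit before DNA mapping.

The measured uncoded error tracks the injected substitution probability
almost exactly, so `calibrate_channel` uses proportional fixed-point
iteration (`p ← p·target/measured`) to a 5 % relative tolerance, typically
converging in one or two rounds. Channels standing in for *compressed
basecallers* are specified by their uncoded error rate (e.g. 5.985 % or
2.153 %) and calibrated the same way: reproducing an actual pruned
basecaller requires GPUs and training data, but its effect on the code is
summarized by the error rate it induces.

Default study conditions: the bundled 8,192-byte public-domain text
excerpt as payload; strand lengths 150 and 300 nt (coded length);
10 replicate seeds per condition in `scripts/acceptance.py`. The default
test run uses 2–3 seeds per stochastic condition and 10⁵-base
characterization sets — sizes chosen so the whole suite stays interactive
while keeping binomial bands meaningful. Fractions are used internally
everywhere; percent appears only in rendered tables and the CLI.

## Pruning mathematics

Pruning operates on named 2-D weight arrays with boolean masks
(True = pruned); fine-tuning between rounds is an abstract callback that
may update surviving values but not masks (an identity callback is the
default — real basecaller retraining is out of scope). Choices:

- The global threshold λ is the x-quantile of pooled |w| over *prunable,
  currently unmasked* weights only (the layers worth compressing are the
  recurrent and linear ones; convolutions and biases are negligible).
  Weights with |w| < λ prune strictly; ties at λ break by lowest flat
  index until the rounded target count is reached, so achieved sparsity is
  within one weight of the target.
- Iterating at per-round fraction p gives sparsity `1 − (1−p)ⁿ`; the
  default p = 0.5 reaches 99.6 % at n = 8. Masks never resurrect.
- Structured pruning ranks whole columns by L1 norm per layer (global
  structured ranking across layers of different column heights is not
  meaningful) and masks the ⌊x·cols⌋ lowest, ties to the lowest index.
- Parameter counts: an LSTM layer with input size I and hidden size H has
  `4·(I·H + H·H + 2H)` parameters (two bias vectors per gate block;
  4,724,736 at I = H = 768, input block 3072×768); an affine layer
  `I·O + O`.

## Known limitations

- The channel is i.i.d. per base; real nanopore errors are bursty and
  sequence-dependent.
- The decoder is substitution-only; a single uncorrected indel would shift
  the bit frame for the rest of a strand.
- Free distance of the rate-1/3 code is capped at 6 by its canonical
  transition structure; at channel error rates of 10–20 % the decoder is
  far beyond its correction radius and decoded error rates in that regime
  characterize failure behaviour, not useful operation.
- Local-alignment measurement slightly undercounts errors at strand
  termini (clipped terminal edits), which marginally lowers measured rates
  at all operating points.
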