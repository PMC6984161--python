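# Methods

## The basecalling problem

A nanopore sequencer reports a raw current time series (a "squiggle") sampled
at a fixed rate while a DNA strand translocates through the pore.  At any
instant the pore holds k consecutive nucleotides (a k-mer), and the measured
current level is a function of that k-mer.  Because translocation is slower
and far less regular than the sampling clock, each base produces a variable
number of samples.  Basecalling is the inverse problem: recover the base
sequence `Y = [y_1..y_M]` from the signal `X = [x_1..x_T]`, with `M < T` and
no alignment between samples and bases given.

`tcncall` treats this as end-to-end sequence labeling: a temporal
convolutional network (TCN) maps each signal window to a per-time-point
probability distribution over the five CTC symbols (A, C, G, T, blank), and
the connectionist temporal classification objective sums over all frame-level
symbol paths that collapse to the target sequence, so no per-sample labels
are needed.

## Pipeline

1. **Standardization.**  Each read is standardized with the median absolute
   deviation: `x' = c * (x - median(x)) / median(|x - median(x)|)`.  The
   median/MAD pair is robust to the outlier spikes common in pore current;
   the constant `c` (default 1.0) only sets the scale of the network input
   and is configurable.  Standardization is per read, before windowing.
2. **Windowing.**  The signal is cut into windows of length T (default 512)
   with stride d (default 118, the setting used for the reported
   experiments; T/4 = 128 is the other documented choice and remains
   configurable).  Two tail policies exist: basecalling uses an extra window
   anchored at `L - T` so no tail samples are lost (the resulting overlap is
   resolved by assembly); training-example construction pads the final
   partial window instead, so window labels partition the read exactly.
3. **Network.**  Stacked residual blocks of two weight-normalized dilated
   causal convolutions, each followed by a gated linear unit in the
   pointwise self-gating form `H ⊗ σ(H)`; a residual connection and final
   ReLU per block, with a 1×1 projection on the skip path when channel
   counts differ (always, in the first block).  Dilations double per block;
   one dilated convolution of filter size k and dilation d sees `(k-1)·d`
   past time points, so the full-scale stack (k=3, dilations 1..16, five
   blocks, 256 filters) accumulates a receptive field of 124 samples, and a
   single convolution in the deepest block sees 32.  Two time-distributed
   fully connected layers (128 then 5 channels, ReLU between them) and a
   softmax yield the T×5 row-stochastic output.  Causality (output row t
   depends only on inputs ≤ t) is enforced by left zero padding of length
   `(k-1)·d` in every convolution and is verified by finite-difference probe
   tests.
4. **CTC.**  `P(Y|X) = Σ_{s: B(s)=Y} Π_t O_t[s_t]`, where B merges
   consecutive repeats then deletes blanks.  The loss is `-log P(Y|X)`.  The
   sum is computed by the forward recursion over the blank-interleaved
   extended label; a literal enumeration over all `5^T` symbol sequences
   serves as the test oracle for small T, and the distribution over collapsed
   sequences is verified to sum to one.
5. **Decoding.**  Greedy (framewise argmax, then collapse; ties break to the
   lowest symbol index) or prefix beam search, which merges all symbol paths
   sharing a collapsed prefix so its score approximates the full path sum
   (and equals it when the beam width covers every prefix).  Default beam
   width 20.
6. **Assembly.**  Per-window fragments are merged left to right at the
   best-scoring suffix/prefix overlap (match +1, mismatch/gap -1, band
   capped at 30% of the shorter fragment, minimum overlap 3); conflicts keep
   the earlier fragment's bases, and a non-positive overlap falls back to
   concatenation so no called bases are dropped.

## Numerical implementation

The network, its gradients, the CTC forward-backward pass, and Adam are
implemented directly in NumPy as a CPU reference implementation: convolutions
reduce to BLAS matrix products per filter tap, and the batched CTC
forward-backward runs in scaled linear space (per-frame renormalization with
accumulated log-normalizers) rather than log space, which avoids underflow on
T = 512 windows at a fraction of the transcendental-function cost.  The
gradient of the loss with respect to the logits is `softmax - posterior
symbol occupancy`; it is validated against finite differences in the test
suite.  Weight normalization (`w = g·v/||v||`) is applied to every dilated
convolution; weights start from a variance-scaled normal with `g = ||v||`,
and bias terms are zero-initialized where enabled (the full-scale default
carries no bias terms at all).  Labels that cannot fit a window's valid
frames (bases + required separator blanks exceed the frame count) are
dropped from training with a logged warning rather than producing infinite
losses.  All randomness flows through explicit seeds; training runs are
bitwise reproducible.

## The squiggle simulator

The simulator provides what re-squiggled real data provides for the original
system — signal with per-base sample boundaries — so the whole pipeline is
trainable and testable without sequencing data.  Its model, and the defaults
that define the package's study conditions:

* **Pore model:** one mean level and noise sd per k-mer, drawn reproducibly —
  levels uniform on 60–140 (picoamp-like units, the span of a real pore
  table), sds uniform on 1.5–3.5.  Edge bases without a full k-mer context
  are not emitted and are trimmed from the recorded truth.
* **Label anchoring:** which base of the resident k-mer names each dwell is
  a real modeling choice.  The default, ``anchor="end"``, attributes a dwell
  to the k-mer's last base — the base about to be shifted out of the pore —
  mirroring re-squiggle labeling, where boundaries are labeled with the
  shifted base.  Labels then lag the signal, so by a base's labeled interval
  its entire k-mer context has been observed, and a causal (past-only)
  network can decode online.  Center anchoring (``anchor="center"``) is also
  available but makes every base's level depend on a base labeled later,
  which a causal model can only resolve by learning systematically delayed
  emission — measurably harder to train.
* **Dwell model:** samples per base; default a shifted geometric with mean 8
  and minimum 2, reproducing the heavy right tail of real translocation
  times (a fixed-dwell option exists for controlled tests).
* **Noise:** per-sample Gaussian with the k-mer's sd times a global
  `noise_sd_scale` (default 1.0).

Deliberately not modeled: methylation-shifted levels, baseline drift, stalls,
adapter/barcode signal, and inter-read level calibration differences.
Passing tests on simulated data therefore demonstrate the pipeline's
correctness and trainability, not performance on real sequencing data.

## Desk-scale configuration and what it achieves

The full-scale architecture (five blocks, 256 filters) is impractical to
train in a test suite, so a reduced configuration is first-class: 2 blocks,
32 filters, windows of T = 256.  Within that constraint the package's
choices are dilations (1, 8) with filter size 5, an FC width of 64, and
zero-initialized bias terms.  The dilation pair matters more than its span
suggests: tap offsets must have gcd 1 across the stack or entire sample
phases become invisible to every output (with dilations (2, 8) each output
can only see same-parity samples).  (1, 8) with five-tap filters tiles a
dense, gap-free 72-sample receptive field — about 9 mean dwells.  Training
uses Adam at an initial rate of 0.02 with a 100-iteration warmup and ×0.4
step decay every 1,200 iterations, batches of 48 overlapping windows
(stride 128), and at most 3,000 iterations.  Because a window's labels are
defined over its whole valid span and the network's emissions are
translation-equivariant, no positional label exclusions are used anywhere
(they would demand a function the architecture cannot represent).

An exact Viterbi decoder over the true k-mer chain (the classical HMM view
of nanopore decoding, used as an independent oracle in the test suite)
recovers simulated sequences at well above 0.9 identity under the default
conditions, confirming the simulated signal carries enough information for
near-complete recovery.  The reduced network at this training budget
recovers substantially less — its CTC output is still blank-dominated with
diffuse base probability, the regime in which prefix beam search (which
sums collapsed-path mass) clearly outperforms the greedy argmax path, so
beam decoding is the recommended setting for models trained at desk scale.
The end-to-end test in the suite measures the recovery level exactly; the
shortfall against a fully converged model is a training-budget effect (the
original full-scale system trained for days on 86 GB of labeled signal),
with held-out identity still climbing when the iteration cap is reached.

## Evaluation definitions

With a read aligned end-to-end against its reference (edlib, global mode,
or SAM CIGAR+MD import for external aligners), and `span` = matches +
mismatches + deletions (the aligned reference length):

* identity = matches/span, and insertion, deletion, mismatch rates are the
  corresponding event counts over span, so identity + mismatch + deletion
  = 1 and total error = insertion + deletion + mismatch.  (Whether the
  denominator is the aligned span or the whole reference differs between
  published tools; this package uses the aligned span.)
* Errors project to 0-based reference coordinates; insertions anchor to the
  position they precede.  An error is **common** to a set of callers when
  every caller has that error type at the same coordinate; a caller's
  common-error proportion is common count over its own count of that type
  (undefined, and excluded from aggregates, for a caller with zero errors
  of a type).
* The six-way taxonomy assigns each error exactly one class with precedence
  homopolymer → Dcm → ordinary: insertion/deletion errors inside a
  reference run of ≥3 identical bases are homopolymer insertions/deletions;
  remaining errors inside a CCTGG/CCAGG occurrence are Dcm errors (that
  motif pair is closed under reverse complement, so one forward scan covers
  both strands); the rest are ordinary insertion, deletion, or
  substitution.  Insertions are judged by the reference base on either side
  of their anchor.

## Known limitations

* The NumPy implementation is single-threaded BLAS-bound; full-scale
  training is out of reach by design.
* Beam search decoding is exact only in the exhaustive-width limit; the
  default width 20 trades accuracy for CPU time.
* Overlap assembly resolves conflicts by keeping the earlier fragment, not
  by consensus voting; with low per-window accuracy this propagates the
  earlier window's errors.
* The model emits no per-base quality values; FASTQ output carries a
  constant placeholder quality.
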