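# Methods

This note records the models, parameter choices and numerical decisions
behind squigglecall, and what the desk-scale tests do and do not
demonstrate.

## Signal model and the squiggle simulator

Nanopore sequencers sample the ionic current through a pore at a much
higher rate than DNA translocates, so the raw trace is
piecewise-near-constant: one level per k-mer context, held for a dwell of
roughly 5–15 samples per base, with additive noise and a per-read
baseline.  The simulator generates exactly this structure:

- **Pore model**: each of the 4^k k-mers (default k = 5) is assigned a
  mean level and spread.  Levels are evenly spaced with jitter and
  shuffled over k-mers, so adjacent levels are well separated relative to
  the within-level sd (separation configurable, default 4 sd).  A real
  pore's response is smoother and correlated between overlapping k-mers;
  the simulator makes no attempt at that, which makes the synthetic task
  *easier* than real basecalling.
- **Context registration**: the k-mer is centered on the base currently
  in the pore, with sequence ends padded by the terminal base.  Real
  pore chemistry does not document its phase; centering is the simplest
  symmetric choice and is a modeling decision, not a claim about the
  device.
- **Dwell**: uniform-integer on [5, 15] samples (mean 10).  Only the
  range is physically motivated; the uniform shape is the
  least-assumptive choice.
- **Noise**: i.i.d. Gaussian per sample (default sd 0.05 of the level
  scale).  No low-frequency drift, stalls, skips or homopolymer-specific
  current behavior — enough to exercise normalization and learning, not
  a kinetic model.
- **Per-read baseline**: one offset (N(0, 2)) and scale (uniform
  0.8–1.2) per read, emulating the per-read calibration that whole-read
  z-scoring removes.
- Every read records exact per-base half-open sample boundaries, which
  downstream stages use as ground truth.

Consequently, a network that excels on simulator data has only been
shown to learn piecewise-constant level codes; real-data accuracy
requires real training data imported through the boundary-TSV dialect.

## Normalization

Whole-read z-score with the *population* standard deviation (divide by
T), recorded as `mean_used`/`sd_used` so results are bit-reproducible.
Windows are cut after normalization, never per-window.  Degenerate reads
(sd < 1e-12) are rejected with a distinct error: a flat signal carries no
sequence information, and silently zeroing it would produce confident
nonsense calls.  Because z-scoring cancels any affine calibration, fast5
signals are used as stored (DAC integers) with no picoampere conversion.

## Network

Defaults: 5 residual convolution blocks of 256 channels (1×3 kernels,
stride 1, zero padding, no convolution bias, batch normalization after
every convolution), 3 bidirectional LSTM layers of 200 hidden units per
direction with separately batch-normalized recurrent and input terms, and
a bias-free fully connected softmax layer over (A, C, G, T, blank).
Layer counts, channels and hidden sizes are configurable; the reduced
configuration used in tests (2 blocks, 32 channels, 1 BiLSTM of 32) keeps
CPU training in minutes.

Decisions the architecture description leaves open, resolved here:

- **BN statistics**: training mode normalizes by the current mini-batch's
  statistics (over batch, and over batch×time for the time-independent
  input-term projection); a single set of exponential running averages
  per normalization site — shared across timesteps — is accumulated
  (momentum 0.1) and used verbatim at inference, making inference
  deterministic.  Per-timestep statistics are not kept.
- **BN shifts in the LSTM**: the recurrent-term and input-term shifts are
  structurally zero (not parameters at all) since they are redundant with
  the cell bias; only the gains and the cell-state BN shift are learned.
- **Gains initialized to 0.1** for the LSTM normalizations, keeping the
  tanh/sigmoid pre-activations out of saturation early in training;
  convolutional BN gains start at 1.
- **Initialization**: variance-scaling (He) for convolution weights,
  per-gate orthogonal blocks for recurrent weights, Glorot-uniform for
  input projections and the FC layer, zero biases; all seed-controlled.
- **Stacking**: every BiLSTM layer's forward/backward outputs are
  concatenated as the next layer's input; the last layer's concatenation
  feeds the FC layer.
- **FC layer carries no bias**: the softmax argument is W_j·H_i.
- ε = 1e-5 inside every batch normalization.

The network, CTC loss and optimizer are implemented on a small
reverse-mode autodiff engine in `squigglecall.autodiff` (double
precision, hand-written vector-Jacobian products, validated against
central finite differences in the test suite).

## CTC loss and training

The loss is −log P(y | x) with the standard blank-augmented lattice and
forward–backward recursions in log space; its gradient with respect to
the logits is softmax minus the lattice-state posterior.  Feasibility
follows the standard expanded-label rule: each base needs a timestep and
each adjacent repeat needs a separating blank; infeasible labels raise
instead of returning an infinite loss.  The implementation is
cross-validated against exhaustive path enumeration (all 5^T paths,
T ≤ 6) in the tests.

Training: Adam, initial learning rate 0.001 (β₁ 0.9, β₂ 0.999).  Segments
are pooled by length (200/400/1000 by default), pools are reshuffled each
epoch, each mini-batch holds one length only, and the per-length batch
queues are visited round-robin.  Choices the training description leaves
open, fixed here and logged with every checkpoint: mini-batch size 8 (a
CPU-friendly default; larger batches give fewer, smoother steps), no
dropout, no gradient clipping.  Checkpoints serialize every parameter,
all BN running statistics, the configuration and the per-epoch loss
curve; save→load→forward is bit-identical.

## Decoding

- **Greedy**: per-timestep argmax (ties to the lowest symbol index),
  collapse consecutive repeats, remove blanks.  A repeated base separated
  by a blank survives collapse, so homopolymers are callable when the
  network emits the separating blank.
- **Beam search**: prefix beam search over *collapsed* sequences,
  tracking blank-ending and nonblank-ending log mass per prefix with
  log-sum-exp arithmetic.  Beams are pruned by total summed mass with one
  amendment: the prefix containing the best *single* path so far is
  always retained.  This preserves the identity "greedy = beam width 1"
  exactly (pure total-mass pruning breaks it on roughly half of random
  matrices), while at widths covering every live prefix the returned
  sequence is provably the posterior argmax.  Ties break
  lexicographically.  Strict monotonicity of the returned posterior in
  the beam width does not hold for any standard beam search (survivor
  sets are not nested); what the tests assert is that the
  exhaustive-width result dominates every smaller width and equals the
  enumerated posterior argmax.
- **Qualities**: qs = 10·log₁₀(P1/P2) with P1, P2 the top-two base
  probabilities at the timestep anchoring the base — the first timestep
  of the argmax run for greedy, the best prefix's emission timestep for
  beam search.  The anchoring timestep is a documented choice; the score
  definition does not specify it.  Qualities are floored at 0 and capped
  at Phred 93 in FASTQ output.

## Whole-read calling and reassembly

Window 300 samples, step 30 (10% of the window), decode batch size 1,100.
A final window flushed against the signal end guarantees every sample is
covered; signals shorter than one window become a single window.

Adjacent slice calls are merged left-to-right.  The expected overlap in
bases is estimated from the window geometry times the running mean
bases-per-sample of previous slices; the new slice is aligned
(suffix–prefix, +1 match / −1 mismatch / −1 gap) against the consensus
tail within that estimate plus a 10-base band.  Consensus on
disagreement: the higher-quality base wins, ties keep the earlier
slice's base; gap columns keep whichever slice has a base there.  Empty
slice calls are skipped; if no overlap scores at least 2, the slice is
concatenated with a logged warning rather than failing the read.
Because merging is pairwise left-to-right, three-way disagreements among
more than two overlapping slices are resolved implicitly by the order of
merging; only the tail of the consensus can change as slices arrive, so
the prefix is streamable.

## Labeling

Segments of a fixed length are cut from boundary-annotated reads at
offsets 0, stride, … (default stride = length, non-overlapping); a
segment's label is the ordered bases whose dwell intervals lie fully
inside the window.  Edge bases partially covered by the window are
excluded — their signal evidence is truncated, and training on them
would teach the network to hallucinate bases it cannot see.  After
labeling, boundary detail is discarded.  Whole reads are z-scored before
cutting so training segments match what the caller feeds the network.
Real-data labeling pipelines (aligner-corrected resquiggling) are out of
scope; their output can be imported through the same boundary-TSV
dialect the simulator writes.

## Evaluation

Global alignment of each call to its known per-read truth with unit edit
costs, not genome mapping — the simulator setting has per-read truth, so
mapping ambiguity does not arise, but this does differ from protocols
that align to a reference genome and ignore unaligned reads.  Traceback
tie policy, fixed because the rates depend on it: prefer an aligned pair
(match/mismatch) over an indel, and a deletion over an insertion.  Rates
are percentages of reference length; the identities
identity = 100 − deletion − mismatch and
error = deletion + insertion + mismatch are asserted on every constructed
`ErrorRates`, not assumed.  Aggregate rates are reference-length-weighted
means.  The Levenshtein implementation is cross-checked against an
independent alignment library in the tests.

## Problem sizes in the tests and acceptance script

The suite trains the reduced network (2 conv blocks, 32 channels, 1
BiLSTM of 32) for 30 epochs on 200 low-noise k = 1 segments of length 200
(~20 bases each) and evaluates on 50 held-out segments; this is the
smallest configuration at which learning progress is unambiguous —
typical runs cut the CTC loss from ~200 to ~10 and the held-out
normalized edit distance to under half the untrained value.  The
ideal-probability round trip uses 100 reads of 100–500 bases with a
5-mer model.  These sizes are the package's chosen desk-scale study
conditions; full-scale training (thousands of real reads, the default
256-channel architecture) uses the same code paths but is not exercised
by the tests.

## Known limitations

- Pure-numpy training is orders of magnitude slower than a GPU
  framework; the default architecture is practical for inference and
  small fine-tuning only.
- The simulator's independence assumptions (levels, noise, dwell) make
  the synthetic task easier than real squiggles; test accuracies do not
  transfer to flowcell data.
- Beam-search decoding is a Python loop over timesteps and beams; width
  50 on long reads is slow (greedy decoding is the practical default on
  CPU).
- Multi-read consensus (assembly/polishing) and adaptive-sampling
  integration are out of scope.
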