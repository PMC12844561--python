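# Methods

`porecall` is a desk-scale re-implementation of a nanopore analysis stack:
a raw-current simulator with ground truth, signal preprocessing, a trainable
CTC basecaller, CTC decoders, an overlap stitcher with FASTQ output, a
per-read CpG 5mC classifier, and the evaluation metrics used to benchmark
both. This note records the models, the parameter choices, the numerical
decisions, and what the synthetic experiments do and do not demonstrate.

## Signal model (simulator)

A read's current trace is generated as

1. an open-pore prefix at `open_pore_pA` (default 240 pA, length drawn
   uniformly from 500–2000 samples) — the elevated current before a molecule
   is captured;
2. for each base `i`, `d_i` samples at the expected level of the 5-mer
   centered on `i`, plus i.i.d. Gaussian noise (`noise_sd_pA`, default
   2.5 pA).

The pore reads five bases at a time, so levels are a function of the 5-mer.
The default pore model draws per-(position, base) contributions with the
central position weighted most, adds a small k-mer-specific deviation, and
maps the result affinely into the 100–200 pA band that characterises the
DNA-bound state on the emulated platform; the open-pore level sits well
above the band. Sequence ends are padded with `A` for level lookup.

Dwell times are `d_i = 1 + NB(mu, r)` with mean
`sampling_rate_hz / speed_bp_s` (4000 Hz / 400 bp/s = 10 samples per base by
default) and negative-binomial overdispersion `dwell_dispersion` (default
0.25, i.e. variance `mu + 0.25 mu^2`; 0 means a fixed dwell of round(mean)
samples). The helicase-regulated translocation speed of 400 bases/s is a
property of the emulated chemistry; the 4 kHz sampling rate is a
configurable assumption chosen to give a realistic ~10 samples per base.

5mC is modeled as an additive level shift on every 5-mer containing the
modified cytosine (symbol `M`): magnitude ~ N(8, 3) pA with a random sign
drawn positive with probability 0.75 per k-mer, all configurable.  The sign
bias gives methylation a dominant current direction with k-mer-specific
exceptions, so averaged methylated and unmethylated profiles differ visibly
— the behaviour seen on the emulated platform — while individual contexts
still scatter; a fully balanced sign distribution (bias 0.5) is available
and makes the per-read detection task a pure signature-memorisation
problem. CpG sites are defined on the forward reference strand
(a CG at position `i` labels the C at `i`); minus-strand reads inherit the
same site. Each read draws its methylation state at a site independently as
Bernoulli(p_site) — reads sample distinct molecules from a population whose
per-site methylation frequency is p_site, which is what bisulfite
frequencies estimate. A `site_consistent` switch instead freezes one state
per site for all reads.

The per-read draw order (open-pore length, dwells, noise) depends only on
the sequence length, so flipping one methylation label under a fixed seed
changes the signal only inside the k-mer spans overlapping that cytosine —
used by tests to verify the locality of the 5mC signature.

Not emulated: signal drift, stalls and sporadic current drops, amplifier
artifacts, colored noise, and the dwell/quality side effects of 5mC (the
real platform shows small dwell and quality differences at methylated CpGs;
only the level shift is modeled, to keep the methylation signal
identifiable). Consequences: passing tests show the pipeline recovers
sequence and methylation from level-encoded signals with realistic dwell
variability, not that it is robust to every artifact of real traces.

## Preprocessing

- **Trimming.** The DNA-bound window is the longest run where a 25-sample
  rolling median stays below the open-pore threshold. The automatic
  threshold is the larger of an Otsu split of the sample histogram and the
  midpoint between the trace's 99.9th percentile (open-pore mode) and its
  median (DNA band center); Otsu alone splits inside the DNA band when the
  open-pore fraction of a long read is small. Traces with < 20 pA of 5–95%
  spread are treated as single-state (kept whole, or rejected as
  "no DNA signal" if their median exceeds 200 pA). A fixed threshold can be
  supplied instead.
- **Normalization.** `(x - median) / MAD` with the raw MAD (no 1.4826
  factor), computed per read over the trimmed region so overlapping chunks
  agree sample-for-sample. Constant segments (MAD = 0) are rejected.
- **Chunking.** Fixed-length windows (default 6000 samples) starting at
  multiples of `chunk_len - overlap` (default overlap 500); the final chunk
  is zero-padded (zero = the post-normalization median) and flagged.
- **Coverage filter (training only).** A chunk is kept iff the fraction of
  its unpadded samples lying inside reference-aligned base spans is
  strictly greater than 0.95 — a chunk at exactly 95% is discarded. The
  denominator is samples, not bases.

## Basecaller

Five 1-D conv layers (batch norm + ReLU; the final layer carries the whole
temporal stride, default 5) feed five recurrent layers — bidirectional
LSTMs by default; a reverse-direction unidirectional mode is provided
because the emulated design is described both ways — then a linear head and
a row softmax over {blank, A, C, G, T} (blank = class 0, the CTC
convention). Residual connections are added wherever consecutive recurrent
layers have matching widths; they markedly speed CPU training and do not
change the layer count. All layers are length-agnostic, so training and
inference may use different chunk lengths.

The networks are implemented in NumPy with numba-compiled LSTM and CTC
kernels and hand-written reverse-mode passes (verified against finite
differences). The recurrent inner loop uses a clamped Padé(7,6) tanh
(|error| < 2e-6) instead of libm calls; this is a ~4x CPU speedup and its
gradient is consistent to well below training noise.

**CTC.** The loss is the negative log of the path-sum over all
blank-augmented alignments, computed by the scaled (probability-space)
forward–backward recursion; the log-likelihood is recovered from the scale
factors and the logit gradient is `softmax - gamma` with `gamma` the
per-frame state posterior. A target is feasible iff
`len(target) + #adjacent-repeats <= frames`; infeasible training examples
are skipped and counted, not errored. The kernel is validated against
exhaustive path enumeration on every random instance with T' <= 6, L <= 3.

**Training.** AdamW under a linear warm-up / cosine decay schedule
(lr(0) = 0, lr(warmup) = lr_max = 0.001 by default) with global gradient-norm
clipping (default 1.0); clipping is what makes learning rates in the 1e-2
range stable for the recurrent stack, and those rates dominate CPU-budget
training. Optionally, training opens with an *alignment-bootstrap* phase: frame-wise cross-entropy against
a single valid CTC path derived from the simulator's exact base→signal
spans — every frame whose center falls in a base's span is labeled with
that base, with a blank carved out between consecutive identical bases.
This is the CTC loss restricted to one alignment (an upper bound of the
full loss); the CTC epochs that follow relax it to the path-sum. The
bootstrap exists because cold-start CTC needs several thousand optimizer
steps before alignments stabilise, which is wasteful on one CPU when exact
alignments are available — and mirrors how training data for the emulated
platform is produced in practice (signals aligned against sequences from an
existing caller). Species-style group sampling weights (e.g. 4:2:2:2) are
supported when examples carry group labels.

The desk-scale preset (`BasecallConfig.tiny`): conv channels
(8, 16, 32, 32, 32), kernels of width 5, stride 5, five bidirectional LSTM
layers of hidden size 32. Checkpoints are single `.npz` archives holding a
version-tagged JSON config plus weight arrays.

## Decoding, stitching, qualities

Greedy (best-path) decoding is the default: per-frame argmax, collapse
repeats, drop blanks; a base's probability is the maximum frame probability
in its run (an upper bound on emission confidence — a documented choice).
Phred quality is `round(-10 log10(1 - p))` clamped to [1, 50] (Sanger
range). Prefix beam search over collapsed sequences is opt-in; with an
exhaustive beam it maximises the true collapsed-sequence posterior, and its
output's frame coordinates come from a Viterbi alignment of the winning
sequence. Note that the posterior of the returned sequence is *not*
guaranteed monotone in beam width under pruning — only the exhaustive-beam
endpoint dominates — a known property of prefix beam search.

Chunks are stitched by cutting each overlap at its midpoint in absolute
signal coordinates (base positions = run centers x stride + chunk offset):
left-chunk bases strictly before the midpoint, right-chunk bases at or
after it. When the base→signal maps agree this is exact and O(n);
alignment-based consensus in overlaps is a documented extension point.
Non-overlapping adjacent chunks are joined whole with a hard-gap warning.
Read/base pass rates use mean Phred >= 10 per read (arithmetic mean of
Phred integers).

## Methylation caller

For each CpG whose 21-base window fits in the read, two feature blocks are
extracted: the window's one-hot sequence (21x4), and per-base signal
statistics (mean, sd, median of the base's normalized samples, dwell in
samples; 21x4). The dwell column is log1p-compressed at the model input to
match the scale of the normalized-signal statistics. Sites within 10 bases
of a read end are skipped and counted. Spans come either from simulator
truth (reference-free) or from decoder frames x stride on called reads; the
two agree when the decode is exact.

Architecture: separate BiLSTMs over each block, concatenation per position,
single-head additive attention producing normalized position weights and a
context vector, a further BiLSTM whose forward/backward end states are
concatenated with the context vector, then two linear layers and a 2-way
softmax giving (P_um, P_m). The exact attention form and hidden sizes are
open design choices; defaults are hidden 16, attention dim 16.

Training: the majority class is downsampled to a 1:1 balance (seeded), 10%
is held out for testing, and Adam runs with gradient-norm clipping under a
*linear decay factor* of 0.4 — read as a linear ramp of the learning rate
down to 0.4x its initial value over the epochs (a per-epoch multiplicative
0.4 is available as `decay_mode="exponential"`, but it extinguishes the
rate within a few epochs, long before the per-k-mer 5mC signatures are
learned). Held-out precision/recall/F1 and ROC/PR AUCs are reported on the
results object. Binary calls use strict `p_m > threshold` (default 0.5; a
probability of exactly 0.5 is called unmethylated).

Two training protocols matter and they are not interchangeable.  The
*balanced protocol* mirrors the treated-sample design: fully methylated and
fully unmethylated runs, features pooled 1:1.  Under it the classifier also
learns to read the *neighbouring* CpGs inside the 21-base window — their
states are perfectly correlated with the center label in that protocol —
so its excellent held-out metrics do not transfer to reads whose sites are
independently methylated.  For frequency estimation the package therefore
trains a *deployment-matched* classifier on mixed-methylation reads
(per-site probabilities Uniform(0,1), labels from simulator truth) drawn
from a genome large enough that almost no site recurs across reads, which
forces k-mer-level rules rather than per-site memorisation and is what
generalises to new genomes (`porecall.experiments.train_frequency_classifier`).

## Evaluation metrics

- **Alignment identity** from CIGAR + NM: columns = M/=/X/I/D lengths;
  mismatches = sum of X when =/X are present, else NM − I − D; identity =
  matching columns / all columns (gap-compressed identity is deliberately
  not used). Calls against known truth use edlib global alignment, whose
  edit distance plays the role of NM.
- **ROC/PR** via scikit-learn (trapezoidal ROC AUC = midrank Mann–Whitney
  under ties; average-precision step-function PR AUC); precision/recall/F1
  computed directly with explicit degenerate-case errors.
- **Site aggregation**: frequency = #(p_m > 0.5)/coverage per forward-strand
  site; Pearson correlation against BS-seq-style tables uses the sample
  covariance with n−1 denominators throughout.
- **Depth curves**: per-site subsampling without replacement (seeded) to
  each target depth, then re-aggregation and re-correlation on shared sites.
- **Error stratification**: reads binned by (1 − identity) into left-closed
  right-open bins, default edges (0, 0.05, …, 0.3, 1.0); empty bins are
  reported as absent, never as zero accuracy.

## Problem sizes in the shipped experiments

The test suite and the reproduction script run everything end-to-end at
sizes a single CPU handles comfortably: a 50 kb genome with 300 reads of
1–2 kb for basecaller training (12 epochs of batch-8 updates on ~2800
short chunks; held-out reads for identity), ~5000 balanced CpG features for
the methylation classifier (85 epochs), a 200 kb genome with 15 000
mixed-methylation features for the frequency classifier (50 epochs), and
~500 CpG sites at ~20x coverage for the frequency-correlation pipeline.
These sizes are the package's own desk-scale study conditions; the
architecture and every pipeline stage are the same at larger scales, only
slower.  At these sizes the held-out basecalling identity reaches roughly
0.8 and is still climbing in both data and epochs — the identity ceiling is
set by the optimizer-update budget, not by the model family — while the
methylation studies saturate their tasks.

## Known limitations

- The simulator's noise is white Gaussian on piecewise-constant levels;
  real traces carry drift, event noise and occasional dropouts, so measured
  identities here characterise the pipeline, not any physical platform.
- The emulated platform's true sampling rate and noise spectrum are not
  public; 4 kHz / 2.5 pA are stated assumptions.
- Greedy decoding underestimates achievable identity slightly; beam search
  recovers some of it at CPU cost.  At desk scale the dominant basecall
  error mode is deletions from an underfit network (the decoded sequence
  scores better than the truth under the model's own CTC loss), so longer
  training, not a different decoder, is the path to higher identity.
- The methylation caller sees only level-shift evidence (by construction of
  the simulator); transfer to modifications that mainly alter dwell is
  untested.
- Stitching trusts the base→signal coordinates; a pathological decode with
  non-monotone coordinates would degrade to the hard-gap join.
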