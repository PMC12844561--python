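# porecall

Trainable nanopore basecalling and CpG 5mC methylation detection from raw
current signals, with a pore-model signal simulator that makes every stage
testable on one CPU.

Nanopore sequencers read DNA by measuring ionic current while a helicase
feeds a single strand through a protein pore; the current at any instant
reflects the ~5 bases occupying the pore, and 5-methylcytosine perturbs it.
Turning these traces back into sequence and methylation state normally
requires platform-scale data and GPUs. `porecall` implements the whole
stack — signal preprocessing, a convolutional + recurrent CTC basecaller,
CTC decoding, overlap stitching with FASTQ output, a BiLSTM-with-attention
5mC classifier, and the standard evaluation metrics — together with a
simulator that emits raw traces with exact ground truth (sequence, per-base
signal spans, per-CpG methylation labels), so training and evaluation run at
desk scale. It is aimed at people developing or studying basecalling and
modification-calling pipelines for emerging nanopore platforms.

## The models

**Basecalling.** A normalized signal chunk `x` passes through five conv
layers (batch norm, ReLU; total temporal stride 5) and five bidirectional
LSTM layers to per-frame probabilities `p_t(c)` over `{blank, A, C, G, T}`.
Training minimises the CTC loss

    L(x, y) = -log Σ_π Π_t p_t(π_t),

the sum over all blank-augmented frame paths `π` that collapse (merge
repeats, drop blanks) to the target `y`, computed by the scaled
forward–backward recursion. Decoding is best-path by default; stitching
cuts chunk overlaps at their signal-coordinate midpoints; qualities are
`round(-10·log10(1-p))` in [1, 50].

**Methylation.** For each CpG, a 21-base window yields one-hot sequence
features and per-base signal summaries (mean, sd, median, dwell). Two
BiLSTM branches, additive attention over the fused positions, a further
BiLSTM and two linear layers produce `(P_um, P_m)` with
`P_um + P_m = 1`. Per-site methylation frequency is the fraction of
covering reads with `P_m > 0.5`, compared against bisulfite-style tables by
Pearson correlation.

**Simulator.** DNA-bound current occupies the 100–200 pA band with
5-mer-dependent levels, preceded by an elevated open-pore segment;
translocation is 400 bases/s against a 4 kHz sampling clock (mean dwell 10
samples/base, negative-binomial dispersion); 5mC adds a k-mer-specific
level shift. See `docs/methods.md` for every assumption and default.

## Worked example

```python
import porecall as pc

# simulate a run with ground truth
pore = pc.build_default_pore_model(seed=1)
params = pc.SimParams(seed=2)
genome = pc.random_reference(20_000, seed=3)
reads, truths = pc.simulate_run(genome, 60, pore, params,
                                read_len_range=(800, 1200))

# train the desk-scale basecaller (alignment-bootstrap + CTC)
chunks, targets, frames = pc.make_basecall_training_set(
    reads[:50], truths[:50], chunk_len=1500, overlap=100)
model = pc.BasecallerModel(chunks, targets, pc.BasecallConfig.tiny(),
                           frame_targets=frames)
fit = model.fit(pc.TrainConfig(batch_size=8, epochs=6, pretrain_epochs=4,
                               lr=1.5e-2, seed=0))
print(fit.summary())

# basecall a held-out read and score it
call, norm = pc.basecall_read(reads[50], fit)
stats = pc.identity_to_truth(call.sequence, truths[50].sequence)
print(f"identity {stats.identity:.3f}  mean quality {call.mean_q:.1f}")
```

Output of this 50-read toy run (about three minutes on one CPU):

```
Basecaller fit summary
======================================================
conv channels        : (8, 16, 32, 32, 32)
recurrent layers     : 5 x bidirectional (hidden 32)
frames per chunk     : 1200 (chunk 6000 / stride 5)
parameters           : 130133
epochs run           : 10
infeasible examples  : 0 (skipped)
train loss           : 410.5753 -> 127.1502
best val loss        : 138.8766
identity 0.659  mean quality 6.6
```

Fifty training reads is deliberately tiny; the shipped end-to-end study
(250 training reads, 12 epochs — see `docs/methods.md` and
`porecall.experiments`) reaches a median held-out identity near 0.80, and
accuracy keeps rising with reads and epochs beyond desk scale.

A command-line interface mirrors the library:
`porecall simulate`, `porecall train-basecaller`, `porecall basecall`,
`porecall train-methcaller`, `porecall methcall`, `porecall evaluate`.

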