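# Methods

## Problem setting

chromacast predicts base-wise NGS read coverage — chromatin accessibility
(ATAC-seq) and the promoter-associated histone mark H3K4me3 (ChIP-seq) — for
plant genomes, from DNA sequence alone. The pipeline has four stages: data
preparation (FASTA + alignments → fixed-length encoded training pairs in an
HDF5 container), model training (sequence-to-coverage networks under a masked
Poisson likelihood), prediction (strand-averaged per-base rate tracks), and
evaluation (Pearson correlation, threshold peak calling, base-wise
precision/recall/F1, precision-recall curves, meta-profiles).

## Data model

**Encoding.** Bases map to 4-vectors in the fixed channel order `C, A, T, G`
(constant `CHANNEL_ORDER`, the single source of truth). `N` encodes as the
uniform vector `[0.25]*4`, which keeps ambiguity distinguishable from padding,
the all-zero vector. With this channel order the reverse complement is a
simultaneous flip of the position and channel axes — a property the strand
tests exploit.

**Chunking.** Each assembly sequence is tiled into non-overlapping windows of
`subseq_len` bp (production default 21 384 bp — long enough for typical plant
gene loci and divisible by ten of the integers 1..20, so strided
down-/up-sampling stays exact at many strides). Only terminal chunks carry
padding; padded positions are masked out of every loss and metric. Windows
consisting entirely of `N` ("gap" chunks) are flagged and dropped from
training and evaluation. Both strands are used: the minus-strand chunk holds
the reverse complement with reversed coordinates, and the (unstranded)
coverage is attached to both strands, reversed on the minus strand.

**Coverage.** ATAC-seq reads are shifted +4 bp (plus strand) / −5 bp (minus
strand) before pileup so read starts mark the Tn5 binding-site centre; shifted
intervals are clipped at zero with length preserved. Coverage is the per-base
count of read-covered positions (reads/bp); whether one counts reads or
fragments is a pipeline choice — we count reads. Replicate samples are
averaged element-wise into one float track per dataset kind. Coverage is
deliberately **not** depth-normalised, and no mean-subtraction/ReLU transform
is applied; the Poisson likelihood operates on raw (averaged) counts.

**Blacklists.** Organellar sequences and unplaced scaffolds are flagged by
whole sequence ID (plain ID list or NCBI-style JSON-lines sequence reports)
and excluded from training and from every evaluation metric.

## Architectures

Three families share the same parts:

* **unet** — strided 1D convolutions (each halving/quartering length) followed
  by mirrored transposed convolutions restoring base resolution;
* **hybrid** — a block of unidirectional LSTM layers inserted at the
  downsampled bottleneck;
* **bihybrid** — the same with bidirectional LSTMs, the appropriate inductive
  bias for unstranded targets.

Every (transposed) convolution is followed by ReLU, then batch normalisation
when enabled; one dropout layer sits between consecutive recurrent layers.
The flagship configuration is 3 conv + 3 transposed conv + 2 BiLSTM + 6 batch
norms + 1 dropout (p = 0.3). Convolution geometry is exact by construction:
total padding `kernel − step` makes a strided convolution map length L to
exactly L/step and the mirrored transposed convolution map it back
(`compute_conv_geometry`); `subseq_len` must be divisible by
`step^n_conv`. As in the standard U-Net design, additive skip connections
join each encoder level to the decoder level of equal resolution
(`skip_connections`, default on); they carry positional detail past the
bottleneck and shortcut gradients to the early motif-detecting filters. A
final 1×1 linear projection emits one channel per predicted dataset.

The network outputs **log** rates; predictions are their exponential, which
is always positive, matching read-count support. Batch norm is placed after
the ReLU (the ordering is not fixed by the family convention; ours is
documented here). Kernel sizes, filter counts and LSTM widths are free
configuration, not constants.

The engine itself is a compact numpy implementation with hand-written
backward passes (im2col convolutions, explicit LSTM recurrences, Adam). Every
backward pass is pinned by finite-difference gradient checks in the test
suite. One subtlety those tests document: gradient checks run at a perturbed
parameter point, because zero-initialised biases put whole channels exactly
on the ReLU kink (upstream ReLUs emit exact zeros), where central differences
are biased although the analytic subgradient convention `relu'(0) = 0` is
standard.

## Training

The loss is the Poisson negative log likelihood for log-rate outputs x and
counts y, `loss = (1/n) Σ exp(x_i) − y_i·x_i`, where the sum and n run over
**unmasked** positions only (padded bases contribute nothing to loss or
gradient — the masking tests assert exact invariance). Optimisation is Adam;
model selection keeps the epoch/checkpoint with the highest validation
Pearson r, computed per predicted dataset over concatenated unmasked
positions and averaged across datasets (a "pooled" single-correlation mode is
configurable).

Two training regimes exist:

* `train` — epochs over a fixed chunk set; fully deterministic given the
  seed, used for the determinism and convergence contracts.
* `train_sampled` — window-resampling augmentation: every batch draws fresh
  random `subseq_len`-bp windows from the training sequences, reverse
  complementing half (targets reversed alongside, valid because coverage is
  strand-symmetric). On desk-scale genomes this is the difference between
  learning and memorising: with fixed tiles a model of even modest capacity
  memorises window identities and validation correlation stays at noise
  level, whereas re-drawn boundaries leave genuine sequence determinants as
  the only stable signal. The end-to-end benchmark uses this regime.

Split utilities assign whole sequence IDs to train/validation (realised
validation base share as close to the requested fraction as whole-ID
assignment allows, seeded shuffling), and `loocv_plan` builds
leave-one-species-out folds for cross-species evaluation.

Defaults (learning rate 1e-3; 2e-3 for the benchmark's small model, batch
size 16–32, no early-stopping patience unless set) are our choices, exposed
in configuration.

## Peak calling and evaluation

**Threshold caller.** Maximal runs of track positions with value ≥ cutoff
(ties included) are merged when separated by ≤ `max_gap` sub-threshold bases
(merge happens before the length filter), then regions shorter than
`min_length` are dropped. The ≤-gap convention is locked by brute-force
oracle tests; anyone comparing against other bedGraph-level callers should
check their gap convention. `min_length`/`max_gap` are typically set to the
library's fragment size; the cutoff comes from inspecting predicted coverage
around transcription starts or from a sweep.

**Metrics.** Pearson r uses an ε-guarded denominator
(`√(Σdx²·Σdy²) + 1e-8`), so constant inputs give 0, never NaN. Peak
agreement is base-wise: peak bases are 1, others 0; TP/FP/FN are counted over
valid positions only (flagged sequences excluded), and precision, recall and
F1 use the convention 0 on zero denominators. Precision-recall curves sweep
the caller's cutoff over a grid; AUPRC is the trapezoid area over
recall-sorted points (cross-checked against scikit-learn's `auc` in tests).
The reference is the positive-fraction baseline — the AUPRC of an
uninformative predictor, equal to the fraction of peak bases among valid
positions.

**Meta-profiles and QC.** `meta_profile` averages coverage at each offset in
±W bp (default 3 kbp) around anchors (e.g. TSS), reading minus-strand anchor
windows right-to-left; truncated windows contribute only available
positions. The enrichment QC divides the profile maximum by the background —
the median of the two outermost 25 % flanks of the window (the "background"
definition is ours and configurable in substance) — and passes at ratio
≥ 2.5, the conventional screening threshold for usable accessibility data. A
zero background reports an infinite ratio and passes.

## Synthetic data

The generator emulates the canonical promoter-proximal geometry: a planted
motif (default the 12-mer `TGACGTCATGCA`, long enough that chance hits are
negligible — ≈ 0.03 expected exact matches per default genome) acts as a
TSS-like anchor. Accessibility peaks centre on the motif; H3K4me3-like peaks
sit `chip_offset` (300 bp) downstream, strand-aware, and are broader (600 vs
200 bp). Bumps are truncated Gaussians (σ = width/4, support ±2σ) of maximum
`peak_height` (6 reads/bp) over a uniform background (0.25 reads/bp);
observed tracks are per-base Poisson samples of the expected rate. Defaults:
64 sequences × 8 192 bp with 4 sites each and 1 024-bp subsequences — sized
for a single CPU while keeping peak-base fractions (≈ 10 % ATAC, ≈ 29 %
ChIP) in the range typical of real accessibility/histone data.

What the generator does **not** emulate: nucleosome positioning, GC bias,
mappability artefacts, replicate variability, motif degeneracy (a single
exact motif, not a PWM), and overdispersion beyond Poisson. Passing tests
therefore demonstrate that the machinery — encoding, masking, likelihood,
architecture, calling, metrics — is correct and that the training loop can
recover sequence-driven signal; they do not certify performance on real
genomes.

## End-to-end benchmark

`chromacast.benchmark.run_synthetic_benchmark` (also behind
`scripts/acceptance.py`) runs the whole pipeline on the default generator:
intra-species split (20 % of sequences to validation), the small bihybrid
(filters 24/16/16, kernel 13, stride 4, 2 BiLSTM × 8 units, dropout 0.1,
skips on; ≈ 29 k parameters), 800 window-sampled steps of batch 32 at
learning rate 2e-3, then strand-averaged prediction on held-out sequences
and scoring against the generator's truth intervals (cutoff sweep 0.5–6.0
step 0.5; operating cutoff 2.0; call geometry 50/50 bp for ATAC and
150/150 bp for ChIP, matched to the bumps' half-maximum support). Problem
sizes are chosen so a full run takes a few minutes on one CPU. Typical
behaviour shows a characteristic phase transition: validation correlation
hovers near zero for a few hundred steps while the motif detector assembles,
then climbs steeply.

## Numerical choices and edge cases

* float64 throughout the NN engine; exact-geometry padding, no silent crops.
* Poisson loss with an all-masked batch is an error, not NaN.
* Pearson needs ≥ 2 unmasked positions; constant inputs give 0 by the ε guard.
* Peak caller rejects non-finite tracks; overlapping peaks are an error when
  rasterised to a mask.
* Rolling-mean smoothing is centred with truncated windows at the edges
  (window 1 is the identity); it is applied at evaluation/prediction time
  only, never baked into stored tracks.
* All randomness flows from explicit seeds through `numpy.random.Generator`;
  training twice with one seed reproduces checkpoints bit-for-bit.

## Known limitations

* The CPU engine is for desk-scale work (10⁵–10⁷ bp); production-scale
  training of 21 384-bp windows on real genomes wants a GPU framework.
* `bdgpeakcall`-style callers may use a strict-gap convention; ours is ≤.
* The intra-species splitter optimises the base share greedily after a
  seeded shuffle; it does not solve the partition problem exactly.
* Fragment-size estimation (for `min_length`/`max_gap`) is taken as user
  input, not computed.
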