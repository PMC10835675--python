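# Methods

## The prediction problem

Hybridization-capture panels enrich genomic targets with designed
oligonucleotide probes before sequencing. Probe-to-probe variation in
hybridization kinetics produces uneven read depth, which wastes sequencing
capacity. `probedepth` models a probe's expected depth as a function of its
sequence alone: given a probe's nucleotide string, predict its log10 read
depth, so that outlier probes can be redesigned or filtered before any
sequencing is done.

## Model

Each probe is presented to the network as two token sequences: the
overlapping k-mers (default k=3, stride 1; a probe of length L yields
L−k+1 tokens) of the forward strand, and the k-mers of its reverse
complement. Hybridization can initiate from either end of the duplex, and
the two strands are chemically distinct, so each strand gets its own
transformer encoder stack with independent weights (the paired attention
module); sharing can be switched on with `tie_encoders` for symmetry
experiments, and `use_pam=False` drops the reverse branch entirely for
ablation.

The input embedding is the sum of a learned token embedding, scaled by
√d_model, and a fixed sinusoidal positional encoding

    PE(pos, 2i)   = sin(pos / base^(2i/d_model))
    PE(pos, 2i+1) = cos(pos / base^(2i/d_model))

with base 1000 by default (10000, the canonical transformer choice, is one
config flag away). The √d_model scaling matters in practice: without it the
unit-amplitude positional signal — identical for every probe — dominates
the 0.02-std token embeddings and a randomly initialized model cannot
distinguish probes well enough to escape the predict-the-mean plateau.

Each encoder layer is a standard post-LayerNorm transformer block:
multi-head self-attention (8 heads by default), GELU feed-forward of width
4·d_model, residual connections, dropout 0.1. The first-token (CLS) vector
of each branch is the pooled representation (masked mean pooling is the
alternative); the two pooled vectors are concatenated and a two-layer head
(hidden width 256, ReLU, then linear) outputs one scalar. Training
minimizes mean squared error against z-scored log10 depths with AdamW,
constant learning rate, and global gradient-norm clipping at 1.0.

The network is implemented on a small reverse-mode automatic
differentiation core over NumPy float32 arrays (`probedepth.autodiff`),
providing exactly the operations the model needs (matmul, embedding
lookup, layer norm, masked softmax, GELU/ReLU, dropout, pooling). Its
gradients are validated against central finite differences in the test
suite. GELU uses the tanh approximation (the BERT convention); the
difference from the erf form is orders of magnitude below training noise.

## Targets and metrics

Observed depths d are mapped to y = (log10(d + c) − μ)/σ with pseudocount
c = 1 by default (so zero-depth probes stay usable) and μ, σ the panel
mean and *population* standard deviation — the normalized targets then
have exactly mean 0 and sd 1, and (c, μ, σ) are stored for inverting the
transform. Evaluation happens on the log10(d + c) scale:

- RMSE: root mean squared log10 error.
- Pearson's r between observed and predicted log10 depth.
- F2acc / F3acc: fraction of probes with |log10(obs) − log10(pred)| below
  log10 2 ≈ 0.301 (resp. log10 3 ≈ 0.477), i.e. predicted within a factor
  of 2 (3) of observed. F3acc ≥ F2acc always, the thresholds being nested.

Cross-validation shuffles probes into size-balanced folds (seeded
permutation, contiguous blocks), trains a fresh model per fold, and —
important for honesty — computes normalization parameters from the
training folds only. Both per-fold and pooled out-of-fold reports are
returned, plus the across-fold RMSE standard deviation.

## Interpretation

**Attention aggregation.** For each branch, layer and head the package
sums softmax attention weights α_ij over all valid (query, key) pairs and
all sequences. For a sequence with T unmasked queries this sum is exactly
T per head — a conservation law the tests assert to 1e-4, which localizes
masking bugs. Because of this conservation the aggregate per-head totals
are *not* informative about what the model attends to on fixed-length
panels; differences between heads, layers and branches live in the
distribution of the weights, which the attention-returning evaluation mode
exposes and the tests compare directly.

**Integrated gradients.** Attributions use the straight-line path from a
baseline embedding to the input embedding, midpoint Riemann sum, 64 steps
by default (128 in the acceptance checks). The baseline replaces every
k-mer token with PAD while keeping CLS and the positional encoding, so the
positional contribution cancels and the attribution isolates sequence
content; a zero-token-embedding baseline is available. Both branches are
attributed; reverse-strand values are mapped back to forward coordinates
(reverse token p ↔ forward token T−1−p) and summed, giving one value per
forward 3-mer. The completeness axiom — attributions summing to
F(x) − F(baseline) — is computed and reported for every result
(tolerance 5% relative + 1e-3 absolute at 128 steps), never assumed; IG is
exact for linear functions, which the tests verify in closed form.

**Depth extremes and k-mer enrichment.** With depths z-scored, the
"extremely high/low" sets at rate ρ (default 0.05) are the probes beyond
the standard-normal quantiles Φ⁻¹(1−ρ) and Φ⁻¹(ρ) — ρ is interpreted
per tail; a total-mass split would use ρ/2 and is one argument away. k-mer
enrichment compares frequency in a subset against a background panel with
a 1/total pseudo-frequency guard against division by zero, and annotates
each k-mer's C+T and G+C composition so base-compositional readings of an
enrichment signal can be inspected alongside per-k-mer ratios. Kendall's
τ-b (scipy) correlates per-probe summed |IG| with externally supplied
thermodynamic metrics; computing those metrics (free energy, secondary
structure) is out of scope — they arrive as a TSV.

## Synthetic panels

The generator draws i.i.d. uniform A/C/G/T probes and assigns

    log10 depth = β0 + β_gc·GC + Σ_m effect_m·count_m + ε,  ε ~ N(0, σ²)

with observed depth 10^(·). Effects are additive on the log10 scale to
match the modelling target, so multiplicative depth effects are additive
here. Motif occurrence counts can be weighted by a triangular positional
profile peaking mid-probe (`center_weighted`) to emulate panels where
mid-probe nucleotides matter most. Defaults define the desk-scale study
condition used throughout: 4,000 probes (3,000 train / 1,000 test) of
60 nt, β0 = 2.5, β_gc = 0.8, one planted motif CTT at +0.3 per
occurrence, σ = 0.15 — giving a true-vs-observed log-depth correlation
near 0.9. What the generator does *not* emulate: hybridization biophysics
(nearest-neighbour ΔG, temperature), probe–probe competition, library
artefacts, and length variation within a panel; a model that recovers the
planted law therefore demonstrates correct plumbing and optimization, not
field performance on real capture data.

## Problem sizes and numerical choices

All heavy checks run at desk scale on one CPU core, a deliberate sizing of
the package's own study conditions:

- Recovery: 2 encoder layers, d_model 64, 4 heads, 30 epochs, batch 64,
  lr 1e-3 on the 3,000/1,000 panel; held-out Pearson r ≈ 0.85 (the
  generator's own ceiling is ≈ 0.87).
- Memorization sanity floor: the full-size default architecture (d_model
  256, 6 layers) must drive training RMSE (normalized) below 0.05 on a
  16-probe panel within 500 steps. This uses lr 5e-4 without weight decay:
  at 1e-3 the ReLU regression head can collapse (all hidden units dead,
  loss frozen), a known small-batch pathology; 5e-4 is stable.
- Stochastic checks (recovery r ≥ 0.6, IG motif localization) are defined
  over three seeds with a ≥ 2-of-3 pass rule and evaluated lazily, so the
  third model only trains when the first two disagree.

Degenerate inputs are rejected rather than patched: constant-depth panels
(zero variance), zero-variance metric inputs, ragged attribution lengths,
k-mers longer than the probe. Ties in Kendall's τ use the τ-b correction.
Checkpoints bundle weights, architecture config, vocabulary and
normalization parameters in one archive, sufficient to predict on new
FASTA without the training panel.

## Known limitations

- Training from natural-language-pretrained encoder weights (used by the
  original full-scale experiments) is supported only as a loading hook;
  random initialization is the default and the only path exercised here.
- BPE tokenization (an ablation baseline in the original study) is not
  implemented — it requires a learned subword vocabulary foreign to a
  4-letter alphabet.
- The PAM-vs-no-PAM ablation is exposed via `use_pam` and unit-tested for
  contract correctness, but the package does not ship a multi-seed
  statistical comparison of the two variants.
- Headline metrics from full-scale published panels (tens of thousands of
  probes, GPU training) are out of reach of the desk-scale conditions;
  the package's checks are property-based by design.
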