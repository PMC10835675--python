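# probedepth

Sequence-only prediction of hybridization-capture probe sequencing depth
with a dual-encoder transformer, for people who design target-enrichment
panels (SNP genotyping, lncRNA capture, synthetic information-storage
pools) and want to flag probes that will be drowned or starved of reads
*before* paying for a sequencing run.

## The model

Capture depth is modelled on the log10 scale. A probe sequence s of length
L is tokenized into its L−k+1 overlapping k-mers (default k=3) twice: once
as written and once as its reverse complement, because hybridization
engages both strands of the duplex. Each strand's tokens pass through a
learned token embedding (scaled by √d_model) plus the sinusoidal encoding

    PE(pos, 2i) = sin(pos / 1000^(2i/d_model)),  PE(pos, 2i+1) = cos(·)

and an independent stack of transformer encoder layers. The two pooled
branch vectors are concatenated and a two-layer feed-forward head outputs
D(s; θ), trained by gradient descent on the mean squared error against
z-scored log10 depths. Predictions are evaluated with RMSE and Pearson's r
on the log10 scale and with factor-of-N accuracies

    F2acc = mean[ |log10 d_obs − log10 d_pred| < log10 2 ],   F3acc likewise with log10 3,

the fraction of probes predicted within 2× (3×) of their observed depth.
Interpretation tooling includes per-layer/per-head attention aggregation,
per-3-mer integrated gradients with an explicit completeness check,
extreme-depth probe extraction via Gaussian tail quantiles, and k-mer
enrichment tables. A synthetic panel generator with a known
sequence-to-depth law (GC effect + planted motifs + log-normal noise)
makes the whole pipeline testable at desk scale. The network runs on a
small NumPy reverse-mode autodiff core — no deep-learning framework
required.

## Worked example

```python
import numpy as np
import probedepth as pp

# a 60-nt panel whose depth law we know: log10 depth = 2.5 + 0.8*GC + 0.3*count(CTT) + noise
panel, _ = pp.simulate_panel(pp.SyntheticParams(n_probes=4000, seed=1))
train_set, test_set = pp.split_panel(panel, 3000)
_, norm = pp.normalize_depths(train_set)

model = pp.DepthModel(pp.ModelConfig(k=3, d_model=64, n_layers=2, n_heads=4,
                                     ffn_dim=256, max_len=64, seed=1))
pp.train(model, train_set, norm,
         pp.TrainConfig(epochs=30, batch_size=64, learning_rate=1e-3,
                        weight_decay=0.0, seed=1))

pred = pp.predict(model, test_set, norm)            # log10(depth+1) scale
obs = pp.observed_log10(test_set, norm)
print(pp.compute_metrics(obs, pred))
```

On this panel the run prints (numbers vary slightly with seed):

```
MetricsReport(rmse=0.1587, pearson_r=0.8768, f2acc=0.944, f3acc=0.997, n=1000)
```

meaning: typical prediction error of 0.16 decades of depth, correlation
0.88 with observed depth — at the generator's own noise ceiling of
r ≈ 0.88 — and 99.7% of held-out probes predicted within a factor of 3 of
their observed depth. Attribution then recovers *why*: integrated
gradients concentrate on the 3-mer windows covering the planted CTT motif.

The `examples/` directory has one short script per capability (simulate,
train/evaluate, cross-validate, interpret, depth extremes). A thin CLI
wraps the same functions for shell use:

```bash
probedepth simulate --n-probes 500 --length 60 --seed 3 --out panel/
probedepth cv --fasta panel/panel.fasta --depths panel/panel.depths.tsv --n-folds 5 --out cv/
```

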