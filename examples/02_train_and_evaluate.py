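"""Train a small dual-encoder depth model and score held-out probes.

Both strands of each probe are tokenized into overlapping 3-mers, encoded
by independent transformer stacks, and the concatenated pooled vectors are
regressed onto normalized log10 depth. Evaluation reports RMSE and Pearson
r on the log10 scale plus factor-of-2/3 accuracies (the fraction of probes
predicted within a factor of 2 or 3 of their observed depth).
"""

import probedepth as pp

panel, _ = pp.simulate_panel(pp.SyntheticParams(n_probes=800, length=40, seed=1))
train_set, test_set = pp.split_panel(panel, 600)
_, norm = pp.normalize_depths(train_set)

model = pp.DepthModel(pp.ModelConfig(
    k=3, d_model=32, n_layers=2, n_heads=4, ffn_dim=128,
    max_len=64, dropout=0.1, head_hidden=32, seed=0,
))
cfg = pp.TrainConfig(epochs=8, batch_size=64, learning_rate=1e-3, seed=0)
model, history = pp.train(model, train_set, norm, cfg)
print(f"training loss: {history[0]:.3f} (epoch 1) -> {history[-1]:.3f} (epoch {len(history)})")

pred = pp.predict(model, test_set, norm)
obs = pp.observed_log10(test_set, norm)
report = pp.compute_metrics(obs, pred)
print(f"held-out RMSE (log10):  {report.rmse:.3f}")
print(f"held-out Pearson r:     {report.pearson_r:.3f}")
print(f"F2acc: {100 * report.f2acc:.1f}%   F3acc: {100 * report.f3acc:.1f}%")
print("(F2acc = fraction of probes whose predicted depth is within 2x of observed;")
print(" an RMSE of 0.3 on the log10 scale corresponds to a typical 2x depth error)")
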