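"""Explain a trained model with attention scores and integrated gradients.

Integrated gradients attribute each prediction to the probe's individual
3-mers: the attribution values sum to the difference between the probe's
prediction and the prediction for an uninformative all-PAD baseline (the
completeness axiom, checked here). Attention aggregation profiles how much
total weight each encoder layer/head assigns — per sequence it must equal
the token count, a conservation law that validates masking.
"""

import numpy as np

import probedepth as pp

# memorize a tiny panel so attributions reflect a real learned mapping
panel, _ = pp.simulate_panel(pp.SyntheticParams(n_probes=16, length=16,
                                                noise_sd=0.3, seed=7))
_, norm = pp.normalize_depths(panel)
model = pp.DepthModel(pp.ModelConfig(k=3, d_model=32, n_layers=2, n_heads=4,
                                     ffn_dim=64, max_len=32, dropout=0.0,
                                     head_hidden=32, seed=0))
pp.train(model, panel, norm, pp.TrainConfig(
    epochs=400, batch_size=16, learning_rate=1e-3, weight_decay=0.0,
    max_steps=400, stop_train_rmse=0.1, rmse_check_every=25))

rec = panel.records[0]
att = pp.integrated_gradients(model, rec, steps=128)
print(f"probe {rec.probe_id}: prediction {att.prediction:+.3f} "
      f"(baseline {att.baseline_prediction:+.3f}, normalized scale)")
tokens = pp.kmer_tokenize(rec.sequence, 3)
top = np.argsort(-np.abs(att.ig_values))[:3]
for i in top:
    print(f"  3-mer {tokens[i]} at position {i}: IG {att.ig_values[i]:+.4f}")
print(f"sum of attributions: {att.ig_values.sum():+.4f}  "
      f"(completeness gap {att.completeness_gap:+.2e})")

summary = pp.attention_scores(model, pp.ProbeSet([rec]))
t = len(tokens) + 1  # + CLS
print(f"attention per head on one {t}-token sequence (should all be {t}):")
print(np.round(summary.forward_scores, 3))
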