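"""Shared fixtures: small synthetic panels and lazily trained models.

The expensive fixtures (recovery models trained on the full desk-scale
panel) are session-scoped and evaluated lazily so cheap unit tests never
pay for them.
"""

from __future__ import annotations

import numpy as np
import pytest

import probedepth as pp


@pytest.fixture(scope="session")
def tiny_panel() -> pp.ProbeSet:
    """16 random probes of 16 nt with noisy composition-driven depths."""
    panel, _ = pp.simulate_panel(
        pp.SyntheticParams(n_probes=16, length=16, noise_sd=0.3, seed=7)
    )
    return panel


@pytest.fixture(scope="session")
def small_model_cfg() -> pp.ModelConfig:
    return pp.ModelConfig(
        k=3, d_model=32, n_layers=2, n_heads=4, ffn_dim=64,
        max_len=64, dropout=0.0, head_hidden=32, seed=0,
    )


@pytest.fixture(scope="session")
def trained_tiny(tiny_panel, small_model_cfg):
    """A small model memorizing the tiny panel; used by interpretation tests."""
    _, norm = pp.normalize_depths(tiny_panel)
    model = pp.DepthModel(small_model_cfg)
    cfg = pp.TrainConfig(
        epochs=400, batch_size=16, learning_rate=1e-3, weight_decay=0.0,
        max_steps=400, stop_train_rmse=0.1, rmse_check_every=25, seed=0,
    )
    pp.train(model, tiny_panel, norm, cfg)
    return model, norm, tiny_panel


# ---------------------------------------------------------------- recovery

RECOVERY_PARAMS = dict(
    n_probes=4000, length=60, beta0=2.5, beta_gc=0.8,
    motif_effects={"CTT": 0.3}, noise_sd=0.15,
)
RECOVERY_SEEDS = (101, 202, 303)


def train_recovery_seed(seed: int):
    """Train one desk-scale recovery model: 3,000 train / 1,000 test probes.

    Returns (model, norm, test set, held-out Pearson r, motif IG contrast).
    The motif contrast is mean |IG| over motif-covering token positions
    minus the non-motif background mean, over 40 test probes.
    """
    params = pp.SyntheticParams(seed=seed, **RECOVERY_PARAMS)
    panel, _ = pp.simulate_panel(params)
    train_set, test_set = pp.split_panel(panel, 3000)
    _, norm = pp.normalize_depths(train_set)
    model = pp.DepthModel(pp.ModelConfig(
        k=3, d_model=64, n_layers=2, n_heads=4, ffn_dim=256,
        max_len=64, dropout=0.1, head_hidden=64, seed=seed,
    ))
    cfg = pp.TrainConfig(epochs=30, batch_size=64, learning_rate=1e-3,
                         weight_decay=0.0, seed=seed)
    pp.train(model, train_set, norm, cfg)
    pred = pp.predict(model, test_set, norm)
    obs = pp.observed_log10(test_set, norm)
    r = float(np.corrcoef(obs, pred)[0, 1])

    motif_vals, bg_vals = [], []
    for rec in test_set.records[:40]:
        att = pp.integrated_gradients(model, rec, steps=32)
        mask = pp.motif_token_mask(rec.sequence, "CTT", k=3)
        if mask.any() and (~mask).any():
            motif_vals.append(np.abs(att.ig_values[mask]).mean())
            bg_vals.append(np.abs(att.ig_values[~mask]).mean())
    contrast = float(np.mean(motif_vals) - np.mean(bg_vals))
    return model, norm, test_set, r, contrast


@pytest.fixture(scope="session")
def recovery_results():
    """Held-out r and IG motif contrast per seed; stops once both checks
    have two successes, so the third seed only trains when needed."""
    results = []
    for seed in RECOVERY_SEEDS:
        _, _, _, r, contrast = train_recovery_seed(seed)
        results.append({"seed": seed, "pearson_r": r, "motif_ig_contrast": contrast})
        r_passes = sum(x["pearson_r"] >= 0.6 for x in results)
        ig_passes = sum(x["motif_ig_contrast"] > 0 for x in results)
        if r_passes >= 2 and ig_passes >= 2:
            break
    return results
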