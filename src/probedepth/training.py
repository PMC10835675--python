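"""Training loop, prediction, evaluation metrics and k-fold cross-validation.

Metrics follow the field's conventions for depth-prediction benchmarks:
RMSE and Pearson's r on the log10 depth scale, and factor-of-N accuracies
F2acc / F3acc — the fraction of probes whose predicted depth is within a
factor of 2 (resp. 3) of the observed depth, i.e. |log10(obs/pred)| below
log10 2 (resp. log10 3). F3acc >= F2acc always, because the thresholds are
nested.

Cross-validation normalizes depths on the training folds only, trains a
fresh model per fold and evaluates on the held-out fold; both per-fold and
pooled out-of-fold reports are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from . import autodiff as ad
from .data_io import (
    FoldAssignment,
    NormalizationParams,
    ProbeSet,
    denormalize,
    make_cv_folds,
    normalize_depths,
    observed_log10,
)
from .model import DepthModel, ModelConfig
from .tokenizer import encode_batch

F2_THRESHOLD = float(np.log10(2.0))
F3_THRESHOLD = float(np.log10(3.0))


@dataclass
class TrainConfig:
    """Optimization hyperparameters."""

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-4
    optimizer: Literal["adam", "adamw", "sgd"] = "adamw"
    weight_decay: float = 0.01
    seed: int = 0
    early_stop_patience: int | None = None
    max_steps: int | None = None  # hard cap on optimizer steps
    stop_train_rmse: float | None = None  # stop once eval-mode train RMSE drops below
    rmse_check_every: int = 10  # epochs between stop_train_rmse checks
    clip_norm: float = 1.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class MetricsReport:
    """RMSE / Pearson r / F2acc / F3acc for one prediction set."""

    rmse: float
    pearson_r: float
    f2acc: float
    f3acc: float
    n: int

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "pearson_r": self.pearson_r,
            "f2acc": self.f2acc,
            "f3acc": self.f3acc,
            "n": self.n,
        }


def compute_metrics(
    observed_log10: np.ndarray,
    predicted_log10: np.ndarray,
    f2_threshold: float = F2_THRESHOLD,
    f3_threshold: float = F3_THRESHOLD,
) -> MetricsReport:
    """Evaluate predictions against observations, both on the log10 scale."""
    obs = np.asarray(observed_log10, dtype=np.float64)
    pred = np.asarray(predicted_log10, dtype=np.float64)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    if obs.std() == 0 or pred.std() == 0:
        raise ValueError("zero variance: Pearson's r undefined")
    err = obs - pred
    rmse = float(np.sqrt(np.mean(err**2)))
    r = float(np.corrcoef(obs, pred)[0, 1])
    abs_err = np.abs(err)
    return MetricsReport(
        rmse=rmse,
        pearson_r=r,
        f2acc=float(np.mean(abs_err < f2_threshold)),
        f3acc=float(np.mean(abs_err < f3_threshold)),
        n=int(obs.size),
    )


def _encode_panel(probes: ProbeSet, model: DepthModel):
    return encode_batch(probes.sequences, model.vocab, prepend_cls=True)


def train(
    model: DepthModel,
    train_probes: ProbeSet,
    params: NormalizationParams,
    cfg: TrainConfig,
) -> tuple[DepthModel, list[float]]:
    """Fit the model in place by minimizing MSE on normalized depths.

    Returns the model and the per-epoch mean training loss history.
    Deterministic for a fixed seed and fixed thread settings.
    """
    if len(train_probes) == 0:
        raise ValueError("empty training set")
    targets = (
        (np.log10(train_probes.depths + params.pseudocount) - params.mean_log10)
        / params.sd_log10
    ).astype(np.float32)
    ids_f, ids_r, mask = _encode_panel(train_probes, model)
    n = len(train_probes)

    rng = np.random.default_rng(cfg.seed)
    if cfg.optimizer == "adamw":
        opt = ad.AdamW(model.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    elif cfg.optimizer == "adam":
        opt = ad.AdamW(model.params, lr=cfg.learning_rate, weight_decay=0.0)
    elif cfg.optimizer == "sgd":
        opt = _SGD(model.params, lr=cfg.learning_rate)
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    history: list[float] = []
    best_loss = np.inf
    stale = 0
    steps = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            pred = model.forward_ids(ids_f[idx], ids_r[idx], mask[idx],
                                     training=True, rng=rng)
            loss = ad.mse(pred, targets[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at step {steps}: {float(loss.data)} "
                    "(consider lowering the learning rate)"
                )
            opt.zero_grad()
            loss.backward()
            ad.clip_grad_norm(model.params.values(), cfg.clip_norm)
            opt.step()
            losses.append(float(loss.data))
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                break
        history.append(float(np.mean(losses)))
        if cfg.stop_train_rmse is not None and (_epoch + 1) % cfg.rmse_check_every == 0:
            pred = model.predict_normalized(ids_f, ids_r, mask)
            if float(np.sqrt(np.mean((pred - targets) ** 2))) < cfg.stop_train_rmse:
                break
        if cfg.max_steps is not None and steps >= cfg.max_steps:
            break
        if cfg.early_stop_patience is not None:
            if history[-1] < best_loss - 1e-6:
                best_loss = history[-1]
                stale = 0
            else:
                stale += 1
                if stale >= cfg.early_stop_patience:
                    break
    return model, history


class _SGD:
    def __init__(self, params: dict[str, ad.Tensor], lr: float) -> None:
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for p in self.params.values():
            if p.grad is not None:
                p.data = (p.data - self.lr * p.grad).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def predict(
    model: DepthModel,
    probes: ProbeSet,
    params: NormalizationParams,
    batch_size: int = 64,
) -> np.ndarray:
    """Eval-mode predictions on the log10(depth + pseudocount) scale, input order."""
    ids_f, ids_r, mask = _encode_panel(probes, model)
    raw = model.predict_normalized(ids_f, ids_r, mask, batch_size=batch_size)
    return denormalize(raw, params)


@dataclass
class CVResult:
    """Outcome of one k-fold cross-validation run."""

    fold_reports: list[MetricsReport]
    pooled_report: MetricsReport
    rmse_std: float
    folds: FoldAssignment
    predictions: pd.DataFrame = field(repr=False)


def cross_validate(
    probes: ProbeSet,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    n_folds: int = 5,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> CVResult:
    """k-fold cross-validation with per-fold renormalization and fresh models.

    Normalization parameters are computed from the training folds only, so
    no information from a held-out fold leaks into its model.
    """
    folds = make_cv_folds(probes, n_folds, seed)
    fold_reports: list[MetricsReport] = []
    rows = []
    for fold in range(n_folds):
        test_ids = set(folds.fold_ids(fold))
        train_set = ProbeSet(
            [r for r in probes if r.probe_id not in test_ids], probes.panel_name
        )
        test_set = ProbeSet(
            [r for r in probes if r.probe_id in test_ids], probes.panel_name
        )
        _, norm = normalize_depths(train_set, pseudocount)
        fold_model_cfg = ModelConfig(**{**_cfg_dict(model_cfg), "seed": model_cfg.seed + fold})
        model = DepthModel(fold_model_cfg)
        fold_train_cfg = TrainConfig(**{**_cfg_dict(train_cfg), "seed": train_cfg.seed + fold})
        train(model, train_set, norm, fold_train_cfg)
        pred = predict(model, test_set, norm)
        obs = observed_log10(test_set, norm)
        fold_reports.append(compute_metrics(obs, pred))
        for rec, o, p in zip(test_set, obs, pred):
            rows.append(
                {
                    "probe_id": rec.probe_id,
                    "fold": fold,
                    "observed_depth": rec.observed_depth,
                    "observed_log10": o,
                    "predicted_log10": p,
                    "abs_log10_error": abs(o - p),
                }
            )
    table = pd.DataFrame(rows)
    pooled = compute_metrics(
        table["observed_log10"].to_numpy(), table["predicted_log10"].to_numpy()
    )
    rmse_std = float(np.std([r.rmse for r in fold_reports], ddof=1))
    return CVResult(
        fold_reports=fold_reports,
        pooled_report=pooled,
        rmse_std=rmse_std,
        folds=folds,
        predictions=table,
    )


def _cfg_dict(cfg) -> dict:
    from dataclasses import asdict

    return asdict(cfg)


def write_predictions_tsv(path, probes: ProbeSet, observed_log10_vals: np.ndarray,
                          predicted_log10: np.ndarray) -> None:
    """Per-probe prediction table: id, raw depth, predicted log10 depth, |error|."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tobserved_depth\tpredicted_log10_depth\tabs_log10_error\n")
        for rec, o, p in zip(probes, observed_log10_vals, predicted_log10):
            fh.write(f"{rec.probe_id}\t{rec.observed_depth:.6g}\t{p:.6f}\t{abs(o - p):.6f}\n")
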