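"""The dual-encoder transformer depth model.

Each probe is presented to the network twice: once as its forward strand
and once as its reverse complement, reflecting that hybridization can
initiate from either end of the duplex. Each strand's k-mer tokens pass
through token + sinusoidal positional embedding and an independent stack of
transformer encoder layers (the paired attention module); the two pooled
branch vectors are concatenated and a two-layer feed-forward head regresses
the normalized log10 sequencing depth. Training minimizes mean squared
error on the normalized depths.

The sinusoidal positional encoding uses

    PE(pos, 2i)   = sin(pos / base^(2i / d_model))
    PE(pos, 2i+1) = cos(pos / base^(2i / d_model))

with base 1000 by default (configurable; 10000 recovers the canonical
transformer encoding).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .data_io import NormalizationParams
from .tokenizer import Vocabulary, build_vocab

_F32 = np.float32


@dataclass
class ModelConfig:
    """Architecture hyperparameters for the depth model."""

    k: int = 3
    d_model: int = 256
    n_layers: int = 6
    n_heads: int = 8
    ffn_dim: int | None = None  # defaults to 4 * d_model
    pe_base: float = 1000.0
    dropout: float = 0.1
    max_len: int = 512
    pooling: str = "first_token"  # or "mean"
    use_pam: bool = True  # paired attention module: encode both strands
    tie_encoders: bool = False
    head_hidden: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.d_model
        if self.d_model % 2 != 0:
            raise ValueError("d_model must be even for sinusoidal encoding")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.pooling not in ("first_token", "mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.pe_base <= 0:
            raise ValueError("pe_base must be positive")


def positional_encoding(max_len: int, d_model: int, base: float = 1000.0) -> np.ndarray:
    """Sinusoidal position matrix of shape (max_len, d_model), float64.

    Column 2i holds sin(pos / base^(2i/d_model)) and column 2i+1 the cosine
    with the same argument, so every (sin, cos) pair lies on the unit circle.
    """
    if d_model % 2 != 0:
        raise ValueError("d_model must be even")
    pos = np.arange(max_len, dtype=np.float64)[:, None]
    i2 = np.arange(0, d_model, 2, dtype=np.float64)[None, :]
    angles = pos / np.power(float(base), i2 / d_model)
    pe = np.empty((max_len, d_model), dtype=np.float64)
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


_BRANCHES = ("fwd", "rev")


class DepthModel:
    """Dual-strand transformer regressor over k-mer token sequences.

    Parameters are float32 ndarrays held in :class:`autodiff.Tensor` leaves.
    The token-embedding table is shared between the two strand encoders;
    encoder weights are independent unless ``config.tie_encoders``.
    """

    def __init__(self, config: ModelConfig, vocab: Vocabulary | None = None) -> None:
        if vocab is None:
            vocab = build_vocab(config.k)
        if vocab.k != config.k:
            raise ValueError(f"vocabulary k={vocab.k} != config k={config.k}")
        self.config = config
        self.vocab = vocab
        self.pe = positional_encoding(config.max_len, config.d_model, config.pe_base).astype(_F32)
        self.params: dict[str, ad.Tensor] = {}
        self._init_params(np.random.default_rng(config.seed))

    # ------------------------------------------------------------------ init

    def _add(self, name: str, data: np.ndarray) -> None:
        self.params[name] = ad.parameter(data)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        d, h = cfg.d_model, cfg.head_hidden
        std = 0.02

        def w(*shape: int) -> np.ndarray:
            return rng.normal(0.0, std, size=shape).astype(_F32)

        self._add("tok_emb", w(len(self.vocab), d))
        branches = ("fwd",) if cfg.tie_encoders else _BRANCHES
        for b in branches:
            for l in range(cfg.n_layers):
                p = f"{b}.l{l}."
                for proj in ("Wq", "Wk", "Wv", "Wo"):
                    self._add(p + proj, w(d, d))
                for bias in ("bq", "bk", "bv", "bo"):
                    self._add(p + bias, np.zeros(d, dtype=_F32))
                self._add(p + "ln1.g", np.ones(d, dtype=_F32))
                self._add(p + "ln1.b", np.zeros(d, dtype=_F32))
                self._add(p + "W1", w(d, cfg.ffn_dim))
                self._add(p + "b1", np.zeros(cfg.ffn_dim, dtype=_F32))
                self._add(p + "W2", w(cfg.ffn_dim, d))
                self._add(p + "b2", np.zeros(d, dtype=_F32))
                self._add(p + "ln2.g", np.ones(d, dtype=_F32))
                self._add(p + "ln2.b", np.zeros(d, dtype=_F32))
        head_in = 2 * d if cfg.use_pam else d
        self._add("head.W1", w(head_in, h))
        self._add("head.b1", np.zeros(h, dtype=_F32))
        self._add("head.W2", w(h, 1))
        self._add("head.b2", np.zeros(1, dtype=_F32))

    def _branch(self, b: str) -> str:
        return "fwd" if self.config.tie_encoders else b

    # --------------------------------------------------------------- forward

    def _linear(self, x: ad.Tensor, name_w: str, name_b: str) -> ad.Tensor:
        w = self.params[name_w]
        b = self.params[name_b]
        if x.ndim > 2:
            # flatten leading dims so the GEMM runs as one 2D matmul
            shape = x.shape
            x2 = ad.reshape(x, (-1, shape[-1]))
            out = ad.add(ad.matmul(x2, w), b)
            return ad.reshape(out, shape[:-1] + (w.shape[1],))
        return ad.add(ad.matmul(x, w), b)

    def embed_ids(self, ids: np.ndarray) -> ad.Tensor:
        """Sum of scaled token embedding and positional encoding; shape (B, T, d_model).

        Token embeddings are multiplied by sqrt(d_model) (the canonical
        transformer convention) so sequence content is not drowned by the
        unit-amplitude sinusoidal positional signal.
        """
        t = ids.shape[-1]
        if t > self.config.max_len:
            raise ValueError(f"sequence of {t} tokens exceeds max_len={self.config.max_len}")
        if ids.max(initial=0) >= len(self.vocab):
            raise ValueError("token id out of vocabulary range")
        tok = ad.embedding(self.params["tok_emb"], ids)
        return ad.add(ad.scale(tok, np.sqrt(self.config.d_model)), ad.constant(self.pe[:t]))

    def _encoder(
        self,
        x: ad.Tensor,
        mask: np.ndarray,
        branch: str,
        training: bool,
        rng: np.random.Generator | None,
        capture: list | None,
    ) -> ad.Tensor:
        cfg = self.config
        b, t, d = x.shape
        nh = cfg.n_heads
        dh = d // nh
        prefix = self._branch(branch)
        for l in range(cfg.n_layers):
            p = f"{prefix}.l{l}."

            def split_heads(h: ad.Tensor) -> ad.Tensor:
                return ad.transpose(ad.reshape(h, (b, t, nh, dh)), (0, 2, 1, 3))

            q = split_heads(self._linear(x, p + "Wq", p + "bq"))
            k = split_heads(self._linear(x, p + "Wk", p + "bk"))
            v = split_heads(self._linear(x, p + "Wv", p + "bv"))
            scores = ad.scale(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
            probs = ad.masked_softmax(scores, mask)
            if capture is not None:
                capture.append(probs.data.copy())
            probs = ad.dropout(probs, cfg.dropout, rng, training)
            ctx = ad.reshape(ad.transpose(ad.matmul(probs, v), (0, 2, 1, 3)), (b, t, d))
            attn_out = ad.dropout(self._linear(ctx, p + "Wo", p + "bo"), cfg.dropout, rng, training)
            x = ad.layer_norm(ad.add(x, attn_out), self.params[p + "ln1.g"], self.params[p + "ln1.b"])
            h = ad.gelu(self._linear(x, p + "W1", p + "b1"))
            h = ad.dropout(self._linear(h, p + "W2", p + "b2"), cfg.dropout, rng, training)
            x = ad.layer_norm(ad.add(x, h), self.params[p + "ln2.g"], self.params[p + "ln2.b"])
        return x

    def _pool(self, x: ad.Tensor, mask: np.ndarray) -> ad.Tensor:
        if self.config.pooling == "first_token":
            return ad.take_index(x, 0, axis=1)
        return ad.masked_mean_pool(x, mask)

    def forward_from_embeddings(
        self,
        emb_f: ad.Tensor,
        emb_r: ad.Tensor,
        mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        capture_attention: dict | None = None,
    ) -> ad.Tensor:
        """Run the network from precomputed input embeddings (IG entry point)."""
        cfg = self.config
        cap_f = [] if capture_attention is not None else None
        u = self._pool(self._encoder(emb_f, mask, "fwd", training, rng, cap_f), mask)
        if cfg.use_pam:
            cap_r = [] if capture_attention is not None else None
            v = self._pool(self._encoder(emb_r, mask, "rev", training, rng, cap_r), mask)
            pooled = ad.concat([u, v], axis=-1)
        else:
            pooled = u
        if capture_attention is not None:
            capture_attention["fwd"] = cap_f
            if cfg.use_pam:
                capture_attention["rev"] = cap_r
        h = ad.relu(self._linear(pooled, "head.W1", "head.b1"))
        out = self._linear(h, "head.W2", "head.b2")
        return ad.reshape(out, (out.shape[0],))

    def forward_ids(
        self,
        ids_f: np.ndarray,
        ids_r: np.ndarray,
        mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        capture_attention: dict | None = None,
    ) -> ad.Tensor:
        """Predict normalized depth for a batch of tokenized probe pairs."""
        emb_f = self.embed_ids(ids_f)
        emb_r = self.embed_ids(ids_r)
        return self.forward_from_embeddings(
            emb_f, emb_r, mask, training=training, rng=rng,
            capture_attention=capture_attention,
        )

    def predict_normalized(self, ids_f: np.ndarray, ids_r: np.ndarray,
                           mask: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Deterministic eval-mode predictions (normalized scale)."""
        out = []
        for lo in range(0, ids_f.shape[0], batch_size):
            hi = lo + batch_size
            pred = self.forward_ids(ids_f[lo:hi], ids_r[lo:hi], mask[lo:hi], training=False)
            out.append(pred.data.astype(np.float64))
        return np.concatenate(out) if out else np.empty(0)

    # ------------------------------------------------------------ checkpoint

    def save(self, path: str | Path, norm_params: NormalizationParams | None = None) -> None:
        """Write a self-contained checkpoint (weights + config + vocabulary)."""
        path = Path(path)
        meta = {
            "config": asdict(self.config),
            "vocab_k": self.vocab.k,
            "norm_params": asdict(norm_params) if norm_params is not None else None,
            "param_names": list(self.params.keys()),
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("meta.json", json.dumps(meta))
            buf = io.BytesIO()
            np.savez(buf, **{k: t.data for k, t in self.params.items()})
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> tuple["DepthModel", NormalizationParams | None]:
        path = Path(path)
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            weights = np.load(io.BytesIO(zf.read("weights.npz")))
            config = ModelConfig(**meta["config"])
            model = cls(config, build_vocab(meta["vocab_k"]))
            for name in meta["param_names"]:
                model.params[name].data = weights[name].astype(_F32)
        norm = meta.get("norm_params")
        return model, (NormalizationParams(**norm) if norm else None)


def mse_loss(predicted: np.ndarray, observed_normalized: np.ndarray) -> float:
    """Mean squared error between two equal-length vectors."""
    predicted = np.asarray(predicted, dtype=np.float64)
    observed_normalized = np.asarray(observed_normalized, dtype=np.float64)
    if predicted.shape != observed_normalized.shape:
        raise ValueError("length mismatch")
    if predicted.size == 0:
        raise ValueError("empty input")
    return float(np.mean((predicted - observed_normalized) ** 2))
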