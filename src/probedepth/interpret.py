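"""Model interpretation: attention aggregation, integrated gradients,
extreme-depth probe extraction and k-mer enrichment.

Attention aggregation sums the softmax attention weights alpha_ij over all
(query, key) token pairs and all sequences, per encoder branch, layer and
head — for an unmasked sequence of T queries each head contributes exactly
T, so deviations localize masking bugs while relative differences between
heads profile where the model attends.

Integrated gradients attribute a probe's predicted depth to its individual
k-mer tokens by integrating the gradient of the prediction along the
straight path from a baseline embedding (all-PAD tokens, i.e. a
no-information probe) to the true input embedding. The completeness axiom
— attributions sum to prediction minus baseline prediction — is computed
and reported for every result, not assumed. Attributions from the
reverse-complement branch are mapped back to forward-strand coordinates
(token p on the reverse strand aligns with token T-1-p on the forward
strand) and summed, giving one importance value per forward 3-mer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import autodiff as ad
from .data_io import ProbeRecord, ProbeSet
from .model import DepthModel
from .tokenizer import PAD, Vocabulary, encode_batch, encode_pair, kmer_tokenize


@dataclass
class AttentionSummary:
    """Aggregated attention mass per branch, layer and head."""

    forward_scores: np.ndarray  # (n_layers, n_heads)
    reverse_scores: np.ndarray | None
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        branches = [("forward", self.forward_scores)]
        if self.reverse_scores is not None:
            branches.append(("reverse", self.reverse_scores))
        for branch, mat in branches:
            for layer in range(mat.shape[0]):
                for head in range(mat.shape[1]):
                    rows.append(
                        {"branch": branch, "layer": layer, "head": head,
                         "score": float(mat[layer, head])}
                    )
        return pd.DataFrame(rows)


@dataclass
class AttributionResult:
    """Integrated-gradient attributions for one probe."""

    probe_id: str
    ig_values: np.ndarray  # one value per forward-strand k-mer token
    prediction: float
    baseline_prediction: float
    completeness_gap: float
    steps: int


def attention_scores(model: DepthModel, probes: ProbeSet, batch_size: int = 32) -> AttentionSummary:
    """Sum attention weights over all valid token pairs, sequences and batches."""
    if len(probes) == 0:
        raise ValueError("empty probe set")
    cfg = model.config
    fwd = np.zeros((cfg.n_layers, cfg.n_heads))
    rev = np.zeros((cfg.n_layers, cfg.n_heads)) if cfg.use_pam else None
    ids_f, ids_r, mask = encode_batch(probes.sequences, model.vocab)
    for lo in range(0, len(probes), batch_size):
        hi = lo + batch_size
        cap: dict = {}
        model.forward_ids(ids_f[lo:hi], ids_r[lo:hi], mask[lo:hi],
                          training=False, capture_attention=cap)
        m = mask[lo:hi]
        # zero out padded queries and keys before summing
        pair_valid = m[:, None, :, None] & m[:, None, None, :]
        for layer, p in enumerate(cap["fwd"]):
            fwd[layer] += (p * pair_valid).sum(axis=(0, 2, 3))
        if rev is not None:
            for layer, p in enumerate(cap["rev"]):
                rev[layer] += (p * pair_valid).sum(axis=(0, 2, 3))
    return AttentionSummary(forward_scores=fwd, reverse_scores=rev,
                            n_sequences=len(probes))


def ig_core(
    forward_fn,
    x: np.ndarray,
    baseline: np.ndarray,
    steps: int,
) -> tuple[np.ndarray, float, float]:
    """Integrated gradients for a generic scalar function of an array input.

    ``forward_fn(batch)`` maps a stacked array of inputs (steps first axis)
    to (values, gradients). Uses the midpoint Riemann rule. Returns
    (attributions with the shape of ``x``, F(x), F(baseline)).
    """
    if steps < 8:
        raise ValueError("steps must be >= 8")
    alphas = (np.arange(steps) + 0.5) / steps
    path = baseline[None] + alphas.reshape((-1,) + (1,) * x.ndim) * (x - baseline)[None]
    _, grads = forward_fn(path)
    avg_grad = grads.mean(axis=0)
    attributions = (x - baseline) * avg_grad
    fx, _ = forward_fn(x[None])
    fb, _ = forward_fn(baseline[None])
    return attributions, float(fx[0]), float(fb[0])


def integrated_gradients(
    model: DepthModel,
    probe: ProbeRecord | str,
    steps: int = 64,
    baseline: str = "pad",
) -> AttributionResult:
    """Per-3-mer integrated-gradient attributions for one probe.

    The baseline replaces every k-mer token with PAD (``"pad"``) or zeroes
    the token-embedding contribution entirely (``"zero"``); the CLS token
    and the positional encoding are common to input and baseline, so their
    attribution is exactly zero and the per-token values isolate sequence
    content. Both strand branches are attributed; reverse-strand values are
    mapped to forward coordinates and summed.
    """
    if baseline not in ("pad", "zero"):
        raise ValueError(f"unknown baseline {baseline!r}")
    if isinstance(probe, str):
        probe = ProbeRecord("probe", probe, 0.0)
    pair = encode_pair(probe.sequence, model.vocab, prepend_cls=True)
    ids_f = pair.forward_ids[None, :]
    ids_r = pair.reverse_ids[None, :]
    t = ids_f.shape[1]
    mask = np.ones((1, t), dtype=bool)

    emb_f = model.embed_ids(ids_f).data[0]  # (T, d)
    emb_r = model.embed_ids(ids_r).data[0]
    pe = model.pe[:t]
    if baseline == "pad":
        pad_row = model.params["tok_emb"].data[PAD]
        base_f = pe + pad_row
        base_r = pe + pad_row
    else:
        base_f = pe.copy()
        base_r = pe.copy()
    # CLS position keeps its own embedding in the baseline: zero attribution there
    base_f = base_f.copy()
    base_r = base_r.copy()
    base_f[0] = emb_f[0]
    base_r[0] = emb_r[0]

    x = np.stack([emb_f, emb_r])  # (2, T, d)
    b = np.stack([base_f, base_r])

    def forward_fn(batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nb = batch.shape[0]
        ef = ad.Tensor(batch[:, 0].astype(np.float32), requires_grad=True)
        er = ad.Tensor(batch[:, 1].astype(np.float32), requires_grad=True)
        out = model.forward_from_embeddings(ef, er, np.ones((nb, t), dtype=bool))
        total = ad.ssum(out)
        total.backward()
        grads = np.stack([ef.grad, er.grad], axis=1).astype(np.float64)
        return out.data.astype(np.float64), grads

    attributions, fx, fb = ig_core(forward_fn, x, b, steps)
    per_pos = attributions.sum(axis=-1)  # (2, T)
    fwd_vals = per_pos[0, 1:]  # drop CLS
    rev_vals = per_pos[1, 1:]
    combined = fwd_vals + rev_vals[::-1]  # reverse token p <-> forward token T-1-p
    gap = float(attributions.sum() - (fx - fb))
    return AttributionResult(
        probe_id=probe.probe_id,
        ig_values=combined,
        prediction=fx,
        baseline_prediction=fb,
        completeness_gap=gap,
        steps=steps,
    )


def positional_importance(attributions: list[AttributionResult]) -> np.ndarray:
    """Mean |IG| per token position across probes of identical length."""
    if not attributions:
        raise ValueError("no attributions given")
    lengths = {a.ig_values.shape[0] for a in attributions}
    if len(lengths) > 1:
        raise ValueError(
            f"probes have different token counts {sorted(lengths)}; "
            "group by length before computing positional importance"
        )
    return np.mean([np.abs(a.ig_values) for a in attributions], axis=0)


def motif_token_mask(sequence: str, motif: str, k: int) -> np.ndarray:
    """Boolean mask over forward k-mer tokens whose window overlaps a motif occurrence."""
    n_tokens = len(sequence) - k + 1
    mask = np.zeros(n_tokens, dtype=bool)
    start = sequence.find(motif)
    while start != -1:
        lo = max(0, start - k + 1)
        hi = min(n_tokens, start + len(motif))
        mask[lo:hi] = True
        start = sequence.find(motif, start + 1)
    return mask


def extreme_depth_sets(
    normalized_depths: np.ndarray,
    ids: list[str],
    rate: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Split out the extreme tails of a standard-normal depth distribution.

    ``rate`` is the per-tail Gaussian tail mass: probes with z above
    Phi^-1(1 - rate) form the high set, below Phi^-1(rate) the low set.
    """
    if not 0 < rate < 0.5:
        raise ValueError("rate must be in (0, 0.5)")
    z = np.asarray(normalized_depths, dtype=np.float64)
    if z.shape[0] != len(ids):
        raise ValueError("ids and depths differ in length")
    hi_thr = stats.norm.ppf(1.0 - rate)
    lo_thr = stats.norm.ppf(rate)
    high = [pid for pid, v in zip(ids, z) if v > hi_thr]
    low = [pid for pid, v in zip(ids, z) if v < lo_thr]
    return high, low


def _kmer_counts(sequences: list[str], k: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    total = 0
    for seq in sequences:
        for kmer in kmer_tokenize(seq, k):
            counts[kmer] = counts.get(kmer, 0) + 1
            total += 1
    return counts, total


def kmer_enrichment(subset: ProbeSet, background: ProbeSet, k: int = 3) -> pd.DataFrame:
    """Per-k-mer frequency comparison between a probe subset and a background.

    Frequencies are k-mer counts over total k-mers per group; the ratio
    subset/background uses a pseudo-frequency of 1/total for absent k-mers
    so it stays finite. Rows sorted by descending ratio. Also annotates the
    base composition of each k-mer so compositional signals (e.g. C+T
    content of depth extremes) can be read off directly.
    """
    if len(subset) == 0 or len(background) == 0:
        raise ValueError("empty probe group")
    sub_counts, sub_total = _kmer_counts(subset.sequences, k)
    bg_counts, bg_total = _kmer_counts(background.sequences, k)
    kmers = sorted(set(sub_counts) | set(bg_counts))
    rows = []
    for kmer in kmers:
        f_sub = sub_counts.get(kmer, 0) / sub_total
        f_bg = bg_counts.get(kmer, 0) / bg_total
        ratio = max(f_sub, 1.0 / sub_total) / max(f_bg, 1.0 / bg_total)
        rows.append(
            {
                "kmer": kmer,
                "freq_subset": f_sub,
                "freq_background": f_bg,
                "ratio": ratio,
                "ct_fraction": sum(c in "CT" for c in kmer) / k,
                "gc_fraction": sum(c in "GC" for c in kmer) / k,
            }
        )
    return pd.DataFrame(rows).sort_values("ratio", ascending=False, ignore_index=True)


def thermo_correlation(
    ig_summary: pd.Series,
    thermo_table: pd.DataFrame,
) -> dict[str, float]:
    """Kendall tau-b between a per-probe IG statistic and thermodynamic metrics.

    ``ig_summary`` is indexed by probe_id (e.g. summed |IG| per probe);
    ``thermo_table`` has a probe_id column and one column per metric.
    """
    merged = thermo_table.set_index("probe_id").join(ig_summary.rename("ig"), how="inner")
    if len(merged) < 10:
        raise ValueError(f"need >= 10 paired observations, got {len(merged)}")
    out: dict[str, float] = {}
    for col in merged.columns:
        if col == "ig":
            continue
        if merged[col].nunique() <= 1:
            raise ValueError(f"column {col!r} is constant; tau undefined")
        tau, _ = stats.kendalltau(merged["ig"], merged[col])
        out[col] = float(tau)
    return out


def summed_abs_ig(attributions: list[AttributionResult]) -> pd.Series:
    """Per-probe sum of |IG| values, indexed by probe_id."""
    return pd.Series(
        {a.probe_id: float(np.abs(a.ig_values).sum()) for a in attributions}
    )


def write_attribution_tsv(path, probes: ProbeSet, attributions: list[AttributionResult],
                          vocab: Vocabulary) -> None:
    """Long-format attribution table: probe_id, position, token, ig_value."""
    by_id = {r.probe_id: r.sequence for r in probes}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tposition\ttoken\tig_value\n")
        for a in attributions:
            tokens = kmer_tokenize(by_id[a.probe_id], vocab.k)
            for pos, (tok, val) in enumerate(zip(tokens, a.ig_values)):
                fh.write(f"{a.probe_id}\t{pos}\t{tok}\t{val:.6g}\n")
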