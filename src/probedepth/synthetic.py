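"""Synthetic probe panels with a known sequence-to-depth law.

Real capture panels tie a probe's sequencing depth to its hybridization
behaviour, which correlates with base composition and sequence motifs. The
generator emulates this with an additive law on the log10 scale:

    log10 depth = beta0 + beta_gc * GC(seq) + sum_m effect_m * count_m(seq) + noise

where count_m is the (optionally position-weighted) number of occurrences
of motif m and the noise is Gaussian with standard deviation ``noise_sd``.
Observed depths are 10 to that power, so effects that are multiplicative
on raw depth are additive here — matching how the model's targets are
normalized. The generator emits exactly the FASTA + depth-TSV formats the
I/O layer reads, plus a ground-truth table for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import ProbeRecord, ProbeSet, write_depth_table, write_fasta

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticParams:
    """Panel-generation settings.

    Defaults produce a desk-scale panel: 4,000 probes of 60 nt (split
    3,000 train / 1,000 test by callers), a GC effect of 0.8 log10 units
    per unit GC fraction, one planted motif (CTT, +0.3 log10 per
    occurrence) and log10-scale noise of 0.15 — giving a true-vs-observed
    log-depth correlation near 0.9.
    """

    n_probes: int = 4000
    length: int = 60
    beta0: float = 2.5
    beta_gc: float = 0.8
    motif_effects: dict[str, float] = field(default_factory=lambda: {"CTT": 0.3})
    positional_profile: str = "uniform"  # or "center_weighted"
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.motif_effects and self.length < max(len(m) for m in self.motif_effects):
            raise ValueError("length must be >= longest motif")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.positional_profile not in ("uniform", "center_weighted"):
            raise ValueError(f"unknown positional_profile {self.positional_profile!r}")


def generate_sequences(params: SyntheticParams) -> list[str]:
    """i.i.d. uniform-random A/C/G/T sequences, deterministic under the seed."""
    rng = np.random.default_rng(params.seed)
    draws = rng.integers(0, 4, size=(params.n_probes, params.length))
    return ["".join(row) for row in _BASES[draws]]


def _motif_weight(params: SyntheticParams, center: float) -> float:
    if params.positional_profile == "uniform":
        return 1.0
    half = (params.length - 1) / 2.0
    return 1.0 - abs(center - half) / half if half > 0 else 1.0


def true_log10_depth(sequence: str, params: SyntheticParams) -> float:
    """Deterministic part of the generator's depth law for one sequence."""
    gc = sum(c in "GC" for c in sequence) / len(sequence)
    depth = params.beta0 + params.beta_gc * gc
    for motif, effect in params.motif_effects.items():
        start = sequence.find(motif)
        while start != -1:
            center = start + (len(motif) - 1) / 2.0
            depth += effect * _motif_weight(params, center)
            start = sequence.find(motif, start + 1)
    return depth


def simulate_panel(params: SyntheticParams) -> tuple[ProbeSet, pd.DataFrame]:
    """Generate a panel plus its ground-truth table.

    Observed depth is 10^(true log10 depth + Gaussian noise); the returned
    DataFrame has columns probe_id, true_log10_depth, observed_depth.
    """
    sequences = generate_sequences(params)
    rng = np.random.default_rng(params.seed + 1)  # noise stream separate from sequences
    truth = np.array([true_log10_depth(s, params) for s in sequences])
    noise = rng.normal(0.0, params.noise_sd, size=params.n_probes)
    observed = np.power(10.0, truth + noise)
    width = len(str(params.n_probes))
    records = [
        ProbeRecord(f"probe_{i + 1:0{width}d}", seq, float(obs))
        for i, (seq, obs) in enumerate(zip(sequences, observed))
    ]
    table = pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "true_log10_depth": truth,
            "observed_depth": observed,
        }
    )
    return ProbeSet(records, panel_name="synthetic"), table


def split_panel(probes: ProbeSet, n_train: int) -> tuple[ProbeSet, ProbeSet]:
    """Deterministic head/tail split into train and test subsets."""
    if not 0 < n_train < len(probes):
        raise ValueError("n_train must leave a nonempty test set")
    return (
        ProbeSet(list(probes.records[:n_train]), probes.panel_name + "_train"),
        ProbeSet(list(probes.records[n_train:]), probes.panel_name + "_test"),
    )


def write_panel(probes: ProbeSet, truth: pd.DataFrame, outdir: str | Path,
                prefix: str = "panel") -> dict[str, Path]:
    """Write FASTA + depth TSV (readable by the I/O layer) + ground-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{prefix}.fasta",
        "depths": outdir / f"{prefix}.depths.tsv",
        "truth": outdir / f"{prefix}.truth.tsv",
    }
    write_fasta(paths["fasta"], probes.ids, probes.sequences)
    write_depth_table(paths["depths"], probes.ids, probes.depths)
    truth[["probe_id", "true_log10_depth"]].to_csv(paths["truth"], sep="\t", index=False)
    return paths
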