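"""Probe panel input/output, depth normalization and cross-validation folds.

A panel is a FASTA file of probe sequences plus a two-column TSV of observed
read depths. Observed depths are modelled on the log10 scale: a probe's
target value is ``(log10(depth + pseudocount) - mean) / sd`` with the mean
and population standard deviation taken over the panel, so that targets are
standard-normal by construction. The parameters are retained so predictions
can be mapped back to the log10-depth scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class ProbeRecord:
    """One oligonucleotide probe with its observed capture depth."""

    probe_id: str
    sequence: str
    observed_depth: float

    def __post_init__(self) -> None:
        if not self.probe_id:
            raise ValueError("probe_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"probe {self.probe_id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"probe {self.probe_id!r}: invalid characters {sorted(bad)} "
                "(alphabet is A/C/G/T/N)"
            )
        if self.observed_depth < 0:
            raise ValueError(f"probe {self.probe_id!r}: negative depth {self.observed_depth}")


@dataclass
class ProbeSet:
    """An ordered collection of probes with unique ids."""

    records: list[ProbeRecord]
    panel_name: str = "panel"

    def __post_init__(self) -> None:
        ids = [r.probe_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate probe ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> ProbeRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.probe_id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def depths(self) -> np.ndarray:
        return np.array([r.observed_depth for r in self.records], dtype=np.float64)

    def subset(self, ids: list[str], panel_name: str | None = None) -> "ProbeSet":
        wanted = set(ids)
        return ProbeSet(
            [r for r in self.records if r.probe_id in wanted],
            panel_name or self.panel_name,
        )


@dataclass(frozen=True)
class NormalizationParams:
    """Log10-scale z-score parameters for a panel's depths."""

    pseudocount: float
    mean_log10: float
    sd_log10: float

    def __post_init__(self) -> None:
        if self.sd_log10 <= 0:
            raise ValueError("sd_log10 must be positive (constant depths?)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")


@dataclass(frozen=True)
class FoldAssignment:
    """Probe-id to fold-index mapping for k-fold cross-validation."""

    n_folds: int
    assignment: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [pid for pid, f in self.assignment.items() if f == fold]


def _read_depth_table(path: Path) -> dict[str, float]:
    depths: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns: {line!r}")
            pid, val = fields[0], fields[1]
            if lineno == 1 or (pid == "probe_id" and not depths):
                # header row is optional
                try:
                    float(val)
                except ValueError:
                    continue
            try:
                depth = float(val)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: cannot parse depth {val!r}") from exc
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth {val!r} for probe {pid!r}")
            if pid in depths:
                raise ValueError(f"{path}:{lineno}: duplicate probe id {pid!r}")
            depths[pid] = depth
    return depths


def read_panel(fasta_path: str | Path, depth_table_path: str | Path,
               panel_name: str | None = None) -> ProbeSet:
    """Join a probe FASTA with its depth table into a :class:`ProbeSet`.

    Records are returned in FASTA order. FASTA entries without a depth are
    dropped with a logged warning; depth entries without a FASTA sequence
    violate the contract and raise.
    """
    fasta_path = Path(fasta_path)
    depth_table_path = Path(depth_table_path)
    depths = _read_depth_table(depth_table_path)

    records: list[ProbeRecord] = []
    fasta_ids: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        pid = rec.id  # biopython already truncates at first whitespace
        if pid in fasta_ids:
            raise ValueError(f"{fasta_path}: duplicate FASTA id {pid!r}")
        fasta_ids.add(pid)
        if pid in depths:
            records.append(ProbeRecord(pid, str(rec.seq).upper(), depths[pid]))

    missing_seq = set(depths) - fasta_ids
    if missing_seq:
        raise ValueError(
            f"{len(missing_seq)} depth-table ids missing from FASTA, "
            f"e.g. {sorted(missing_seq)[:3]}"
        )
    dropped = len(fasta_ids) - len(records)
    if dropped:
        logger.warning("%d probe(s) without depth dropped from %s", dropped, fasta_path.name)
    if not records:
        raise ValueError("no probes shared between FASTA and depth table")
    return ProbeSet(records, panel_name or fasta_path.stem)


def normalize_depths(
    probes: ProbeSet, pseudocount: float = 1.0
) -> tuple[np.ndarray, NormalizationParams]:
    """Z-score log10(depth + pseudocount) with the population standard deviation.

    Returns the per-probe normalized values (mean 0, sd 1 by construction)
    and the parameters needed to invert the transform.
    """
    if len(probes) < 2:
        raise ValueError("need at least 2 probes to normalize")
    d = probes.depths + pseudocount
    if np.any(d <= 0):
        raise ValueError("depth + pseudocount must be positive for log10")
    log_d = np.log10(d)
    mean = float(log_d.mean())
    sd = float(log_d.std())  # population sd: exact unit variance afterwards
    if sd == 0:
        raise ValueError("constant depths: zero variance after log10 transform")
    params = NormalizationParams(pseudocount=pseudocount, mean_log10=mean, sd_log10=sd)
    return (log_d - mean) / sd, params


def denormalize(values: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Map normalized values back to the log10(depth + pseudocount) scale."""
    return np.asarray(values, dtype=np.float64) * params.sd_log10 + params.mean_log10


def observed_log10(probes: ProbeSet, params: NormalizationParams) -> np.ndarray:
    """Observed depths on the same log10(depth + pseudocount) scale as predictions."""
    return np.log10(probes.depths + params.pseudocount)


def make_cv_folds(probes: ProbeSet, n_folds: int, seed: int) -> FoldAssignment:
    """Randomly partition probe ids into ``n_folds`` size-balanced folds."""
    n = len(probes)
    if not 2 <= n_folds <= n:
        raise ValueError(f"n_folds must be in [2, {n}], got {n_folds}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment: dict[str, int] = {}
    ids = probes.ids
    for fold, chunk in enumerate(np.array_split(order, n_folds)):
        for idx in chunk:
            assignment[ids[idx]] = fold
    return FoldAssignment(n_folds=n_folds, assignment=assignment, seed=seed)


def write_depth_table(path: str | Path, ids: list[str], depths: np.ndarray) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tdepth\n")
        for pid, d in zip(ids, depths):
            fh.write(f"{pid}\t{d:.6g}\n")


def write_fasta(path: str | Path, ids: list[str], sequences: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, seq in zip(ids, sequences):
            fh.write(f">{pid}\n{seq}\n")
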