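"""Overlapping k-mer tokenization for both DNA strands.

A probe of length L is tokenized into the L - k + 1 overlapping k-mers read
with a stride-one sliding window; the same is done for its reverse
complement, so the model sees the sequence as it exists in solution: two
antiparallel strands. The vocabulary is the full set of 4^k nucleotide
k-mers in lexicographic order plus three special tokens (PAD for batching,
UNK for ambiguity codes, CLS as a sequence-level summary position).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np

PAD, UNK, CLS = 0, 1, 2
PAD_TOKEN, UNK_TOKEN, CLS_TOKEN = "<pad>", "<unk>", "<cls>"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Watson–Crick reverse complement (A<->T, C<->G, N self-paired)."""
    for pos, ch in enumerate(sequence):
        if ch not in "ACGTN":
            raise ValueError(f"invalid nucleotide {ch!r} at position {pos}")
    return sequence.translate(_COMPLEMENT)[::-1]


def kmer_tokenize(sequence: str, k: int) -> list[str]:
    """All overlapping k-mers of ``sequence``, left to right, stride one."""
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} < k={k}")
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


def merge_tokens(tokens: list[str]) -> str:
    """Invert :func:`kmer_tokenize` by overlap-merging consecutive k-mers."""
    if not tokens:
        return ""
    return tokens[0] + "".join(t[-1] for t in tokens[1:])


@dataclass(frozen=True)
class Vocabulary:
    """k-mer token vocabulary: PAD=0, UNK=1, CLS=2, then 4^k k-mers in lexicographic order."""

    k: int
    token_to_id: dict[str, int]
    id_to_token: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.id_to_token)

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, UNK)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i, tok in enumerate(self.id_to_token):
                fh.write(f"{tok}\t{i}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        tokens: list[str] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                tok, idx = line.rstrip("\n").split("\t")
                assert int(idx) == len(tokens), "vocabulary file out of order"
                tokens.append(tok)
        k = len(tokens[-1])
        return cls(k=k, token_to_id={t: i for i, t in enumerate(tokens)},
                   id_to_token=tuple(tokens))


def build_vocab(k: int) -> Vocabulary:
    """Deterministic vocabulary of all 4^k k-mers plus the 3 special tokens."""
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in [1, 8], got {k}")
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]  # lexicographic
    tokens = [PAD_TOKEN, UNK_TOKEN, CLS_TOKEN] + kmers
    return Vocabulary(
        k=k,
        token_to_id={t: i for i, t in enumerate(tokens)},
        id_to_token=tuple(tokens),
    )


@dataclass(frozen=True)
class TokenizedPair:
    """Token ids for a probe's forward strand and its reverse complement."""

    forward_ids: np.ndarray
    reverse_ids: np.ndarray
    seq_length: int

    def __post_init__(self) -> None:
        if self.forward_ids.shape != self.reverse_ids.shape:
            raise ValueError("forward and reverse token sequences differ in length")


def _ids(tokens: list[str], vocab: Vocabulary) -> np.ndarray:
    return np.array(
        [vocab.token_to_id.get(t, UNK) if "N" not in t else UNK for t in tokens],
        dtype=np.int64,
    )


def encode_pair(sequence: str, vocab: Vocabulary, prepend_cls: bool = True) -> TokenizedPair:
    """Tokenize both strands of ``sequence`` to id arrays.

    k-mers containing N map to UNK; a CLS id is prepended to both strands
    when ``prepend_cls`` (the model's first-token pooling reads it).
    """
    fwd = _ids(kmer_tokenize(sequence, vocab.k), vocab)
    rev = _ids(kmer_tokenize(reverse_complement(sequence), vocab.k), vocab)
    if prepend_cls:
        fwd = np.concatenate(([CLS], fwd))
        rev = np.concatenate(([CLS], rev))
    return TokenizedPair(forward_ids=fwd, reverse_ids=rev, seq_length=len(sequence))


def encode_batch(
    sequences: list[str], vocab: Vocabulary, prepend_cls: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode a list of sequences into padded id matrices and a validity mask.

    Returns (forward_ids, reverse_ids, mask), each of shape (n, T_max); PAD
    fills the tail of shorter sequences and mask is True on real tokens.
    """
    pairs = [encode_pair(s, vocab, prepend_cls) for s in sequences]
    lengths = [p.forward_ids.shape[0] for p in pairs]
    t_max = max(lengths)
    n = len(pairs)
    fwd = np.full((n, t_max), PAD, dtype=np.int64)
    rev = np.full((n, t_max), PAD, dtype=np.int64)
    mask = np.zeros((n, t_max), dtype=bool)
    for i, (p, ln) in enumerate(zip(pairs, lengths)):
        fwd[i, :ln] = p.forward_ids
        rev[i, :ln] = p.reverse_ids
        mask[i, :ln] = True
    return fwd, rev, mask
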