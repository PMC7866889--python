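"""Overlapping k-mer tokenization against a complete 4^k vocabulary.

A DNA sequence of length L is turned into a stream of integer token ids by
sliding a window of width k along it (default stride 1, i.e. maximally
overlapping).  The vocabulary is the full set of 4^k k-mers over {A,C,G,T},
ordered lexicographically (A < C < G < T) so that token ids are stable across
runs and machines.  For k = 3 the vocabulary holds 64 entries and a 41-bp
window yields 39 tokens.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_BASE_TO_ID = {base: i for i, base in enumerate(ALPHABET)}

MAX_K = 8  # 4^8 = 65,536 entries; beyond this the table stops being useful


@dataclass(frozen=True)
class KmerVocabulary:
    """Bijection between all 4^k DNA k-mers and ids in [0, 4^k).

    Ids follow lexicographic order of the k-mers, which coincides with
    reading each k-mer as a base-4 number under A=0, C=1, G=2, T=3.
    """

    k: int
    kmers: tuple[str, ...]
    kmer_to_id: dict[str, int] = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.kmers)

    def id_of(self, kmer: str) -> int:
        try:
            return self.kmer_to_id[kmer]
        except KeyError:
            raise KeyError(f"k-mer {kmer!r} is not a {self.k}-mer over {ALPHABET}") from None

    def kmer_of(self, token_id: int) -> str:
        if not 0 <= token_id < self.size:
            raise IndexError(f"token id {token_id} outside [0, {self.size})")
        return self.kmers[token_id]

    def to_tsv(self, path) -> None:
        """Export as two-column TSV (kmer, id) for audit."""
        with open(path, "w") as fh:
            for i, kmer in enumerate(self.kmers):
                fh.write(f"{kmer}\t{i}\n")

    @classmethod
    def from_tsv(cls, path) -> "KmerVocabulary":
        mapping: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                kmer, sid = line.split("\t")
                mapping[kmer] = int(sid)
        if not mapping:
            raise ValueError(f"empty vocabulary file: {path}")
        k = len(next(iter(mapping)))
        vocab = build_vocabulary(k)
        if mapping != vocab.kmer_to_id:
            raise ValueError(f"{path} is not the complete lexicographic {k}-mer vocabulary")
        return vocab


@dataclass(frozen=True)
class TokenStream:
    """Ordered token ids produced from one sequence.

    len(token_ids) == (source_length - k) // stride + 1 and every id lies in
    [0, 4^k).
    """

    token_ids: tuple[int, ...]
    source_length: int
    k: int
    stride: int

    def __len__(self) -> int:
        return len(self.token_ids)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.token_ids, dtype=np.int64)


def build_vocabulary(k: int) -> KmerVocabulary:
    """Build the complete lexicographic vocabulary of all 4^k k-mers.

    Raises ValueError for k outside [1, 8].
    """
    if not isinstance(k, int) or isinstance(k, bool):
        raise ValueError(f"k must be an integer, got {k!r}")
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    kmers = tuple("".join(p) for p in itertools.product(ALPHABET, repeat=k))
    return KmerVocabulary(k=k, kmers=kmers, kmer_to_id={s: i for i, s in enumerate(kmers)})


def encode_sequence(sequence: str, k: int) -> np.ndarray:
    """Map a sequence straight to stride-1 token ids without building strings.

    Vectorized path used by the training loop; identical output to
    ``tokenize(seq, build_vocabulary(k), stride=1)``.
    """
    codes = _sequence_codes(sequence)
    if len(codes) < k:
        raise ValueError(f"sequence length {len(codes)} shorter than k={k}")
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    return windows @ powers


def _sequence_codes(sequence: str) -> np.ndarray:
    codes = np.empty(len(sequence), dtype=np.int64)
    for pos, base in enumerate(sequence):
        code = _BASE_TO_ID.get(base)
        if code is None:
            raise ValueError(f"unknown character {base!r} at position {pos} (0-based)")
        codes[pos] = code
    return codes


def tokenize(sequence: str, vocab: KmerVocabulary, stride: int = 1) -> TokenStream:
    """Slide a k-wide window along ``sequence`` and map each k-mer to its id.

    Raises ValueError if the sequence is shorter than k, contains a character
    outside {A,C,G,T} (the position is named), or stride < 1.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    k = vocab.k
    codes = _sequence_codes(sequence)
    if len(codes) < k:
        raise ValueError(f"sequence length {len(sequence)} shorter than k={k}")
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)[::stride]
    ids = windows @ powers
    return TokenStream(
        token_ids=tuple(int(i) for i in ids),
        source_length=len(sequence),
        k=k,
        stride=stride,
    )


def detokenize(stream: TokenStream, vocab: KmerVocabulary) -> str:
    """Reconstruct the source sequence by overlap-merging a stride-1 stream.

    Consecutive tokens must agree on their k-1 overlapping bases; a mismatch
    means the stream is corrupt.  Only stride 1 is lossless, so anything else
    is rejected.
    """
    if stream.stride != 1:
        raise ValueError(f"detokenize requires stride 1, got stride {stream.stride}")
    if not stream.token_ids:
        raise ValueError("empty token stream")
    if stream.k != vocab.k:
        raise ValueError(f"stream k={stream.k} does not match vocabulary k={vocab.k}")
    first = vocab.kmer_of(stream.token_ids[0])
    parts = [first]
    prev = first
    for idx, token_id in enumerate(stream.token_ids[1:], start=1):
        kmer = vocab.kmer_of(token_id)
        if kmer[:-1] != prev[1:]:
            raise ValueError(
                f"inconsistent overlap between tokens {idx - 1} ({prev}) and {idx} ({kmer})"
            )
        parts.append(kmer[-1])
        prev = kmer
    sequence = "".join(parts)
    if len(sequence) != stream.source_length:
        raise ValueError(
            f"reconstructed length {len(sequence)} != recorded source length "
            f"{stream.source_length}"
        )
    return sequence
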