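"""Labelled fixed-length sequence windows: reading, validation, splitting.

The unit of data is a 41-bp DNA window centered on an adenine; the label says
whether that central A is N6-methylated (1) or not (0).  Files carry one class
each — the label comes from the file's role, not from the records — and may be
FASTA or plain text with one sequence per line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
DEFAULT_WINDOW_LENGTH = 41


def center_index(window_length: int) -> int:
    """0-based index of the central base: ceil(L/2) in 1-based coordinates.

    For L=41 this is 1-based position 21, i.e. index 20.
    """
    return math.ceil(window_length / 2) - 1


class WindowValidationError(ValueError):
    """A window failed strict validation; the message names id and reason."""


@dataclass(frozen=True)
class LabelledWindow:
    """One fixed-length window plus its binary methylation label."""

    sequence: str
    label: int
    id: str | None = None

    def validate(self, window_length: int = DEFAULT_WINDOW_LENGTH) -> None:
        name = self.id or "<unnamed>"
        if self.label not in (0, 1):
            raise WindowValidationError(f"{name}: label must be 0 or 1, got {self.label}")
        if len(self.sequence) != window_length:
            raise WindowValidationError(
                f"{name}: length {len(self.sequence)} != required {window_length}"
            )
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise WindowValidationError(
                f"{name}: alphabet must be ACGT, found {sorted(bad)}"
            )
        mid = center_index(window_length)
        if self.sequence[mid] != "A":
            raise WindowValidationError(
                f"{name}: center base (1-based position {mid + 1}) is "
                f"{self.sequence[mid]!r}, expected 'A'"
            )


@dataclass
class Dataset:
    """An ordered collection of same-length labelled windows."""

    windows: list[LabelledWindow]
    name: str = "dataset"
    window_length: int = DEFAULT_WINDOW_LENGTH
    n_dropped: int = 0  # records discarded during lenient reading

    def __post_init__(self) -> None:
        for w in self.windows:
            if len(w.sequence) != self.window_length:
                raise ValueError(
                    f"window {w.id or '<unnamed>'} has length {len(w.sequence)}, "
                    f"dataset requires {self.window_length}"
                )

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[LabelledWindow]:
        return iter(self.windows)

    def __getitem__(self, i: int) -> LabelledWindow:
        return self.windows[i]

    @property
    def n_positive(self) -> int:
        return sum(w.label for w in self.windows)

    @property
    def n_negative(self) -> int:
        return len(self.windows) - self.n_positive

    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=np.int64)

    def sequences(self) -> list[str]:
        return [w.sequence for w in self.windows]

    def subset(self, indices: Sequence[int], name: str | None = None) -> "Dataset":
        return Dataset(
            windows=[self.windows[i] for i in indices],
            name=name or self.name,
            window_length=self.window_length,
        )


@dataclass(frozen=True)
class FoldSplit:
    """Assignment of every window to exactly one of ``fold_count`` folds."""

    fold_count: int
    assignments: np.ndarray  # shape (n,), values in [0, fold_count)

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def _normalize(raw: str) -> str:
    return raw.strip().upper()


def _iter_records(path: Path, format: str) -> Iterator[tuple[str, str]]:
    if format == "fasta":
        for record in SeqIO.parse(str(path), "fasta"):
            yield record.id, _normalize(str(record.seq))
    elif format == "lines":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                seq = _normalize(line)
                if seq:
                    yield f"{path.stem}_{lineno}", seq
    else:
        raise ValueError(f"unsupported format {format!r}; expected 'fasta' or 'lines'")


def sniff_format(path) -> str:
    """Guess 'fasta' vs 'lines' from the first non-blank character."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.lstrip().startswith(">") else "lines"
    return "lines"


def read_windows(
    path,
    format: str = "auto",
    label: int = 1,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    strict: bool = True,
    name: str | None = None,
) -> Dataset:
    """Read one file of windows, all carrying ``label``.

    In strict mode any record violating the window invariants (length,
    ACGT-only alphabet, central A) raises :class:`WindowValidationError`.  In
    lenient mode invalid records are dropped; the count is logged and stored
    on the returned dataset as ``n_dropped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if format == "auto":
        format = sniff_format(path)
    windows: list[LabelledWindow] = []
    dropped = 0
    for rec_id, seq in _iter_records(path, format):
        window = LabelledWindow(sequence=seq, label=label, id=rec_id)
        try:
            window.validate(window_length)
        except WindowValidationError:
            if strict:
                raise
            dropped += 1
            continue
        windows.append(window)
    if dropped:
        logger.warning("dropped %d invalid record(s) while reading %s", dropped, path)
    return Dataset(
        windows=windows,
        name=name or path.stem,
        window_length=window_length,
        n_dropped=dropped,
    )


def concat(datasets: Iterable[Dataset], name: str = "combined") -> Dataset:
    datasets = list(datasets)
    lengths = {d.window_length for d in datasets}
    if len(lengths) != 1:
        raise ValueError(f"cannot concatenate datasets with window lengths {sorted(lengths)}")
    windows = [w for d in datasets for w in d.windows]
    return Dataset(windows=windows, name=name, window_length=lengths.pop())


def write_windows(dataset: Dataset, path, format: str = "fasta", label: int | None = None) -> int:
    """Write windows (optionally only those with ``label``) to one file.

    Returns the number of records written.  The lines format stores bare
    sequences, so record ids survive a round-trip only through FASTA.
    """
    selected = [w for w in dataset if label is None or w.label == label]
    path = Path(path)
    if format == "fasta":
        records = [
            SeqRecord(Seq(w.sequence), id=w.id or f"{dataset.name}_{i}", description="")
            for i, w in enumerate(selected)
        ]
        SeqIO.write(records, str(path), "fasta")
    elif format == "lines":
        with open(path, "w") as fh:
            for w in selected:
                fh.write(w.sequence + "\n")
    else:
        raise ValueError(f"unsupported format {format!r}")
    return len(selected)


def write_manifest(dataset: Dataset, path, fold_split: FoldSplit | None = None) -> None:
    """TSV manifest: id, sequence, label and (when given) fold assignment."""
    with open(path, "w") as fh:
        header = "id\tsequence\tlabel" + ("\tfold" if fold_split is not None else "")
        fh.write(header + "\n")
        for i, w in enumerate(dataset):
            row = f"{w.id or i}\t{w.sequence}\t{w.label}"
            if fold_split is not None:
                row += f"\t{fold_split.assignments[i]}"
            fh.write(row + "\n")


def stratified_kfold(dataset: Dataset, fold_count: int, seed: int = 0) -> FoldSplit:
    """Partition the dataset into ``fold_count`` class-stratified folds.

    Deterministic given ``seed``.  Per-fold positive fraction deviates from
    the global fraction by at most one sample.
    """
    if fold_count < 2:
        raise ValueError(f"fold_count must be >= 2, got {fold_count}")
    labels = dataset.labels()
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if min(n_pos, n_neg) < fold_count:
        raise ValueError(
            f"need at least {fold_count} samples of each class for {fold_count} folds; "
            f"have {n_pos} positive and {n_neg} negative"
        )
    splitter = StratifiedKFold(n_splits=fold_count, shuffle=True, random_state=seed)
    assignments = np.full(len(dataset), -1, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    assert (assignments >= 0).all()
    return FoldSplit(fold_count=fold_count, assignments=assignments)


def holdout_split(
    dataset: Dataset, test_fraction: float, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Disjoint stratified train/test split whose union is the input.

    ``test_fraction`` must lie strictly in (0, 1) and leave at least one
    sample of each class on both sides.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    labels = dataset.labels()
    if len(np.unique(labels)) < 2:
        raise ValueError("holdout_split requires both classes present")
    indices = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        indices, test_size=test_fraction, random_state=seed, stratify=labels
    )
    train = dataset.subset(sorted(train_idx), name=f"{dataset.name}_train")
    test = dataset.subset(sorted(test_idx), name=f"{dataset.name}_test")
    for part, role in ((train, "train"), (test, "test")):
        if part.n_positive == 0 or part.n_negative == 0:
            raise ValueError(
                f"{role} part lost a class entirely (fraction {test_fraction} too extreme "
                f"for {len(dataset)} windows)"
            )
    return train, test
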