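"""Synthetic 41-bp center-A datasets with planted, class-enriched motifs.

Real 6mA training sets consist of fixed-length windows centered on an adenine
where the positive class is enriched for short purine motifs (GAGG, AGG, AG)
relative to negatives sampled to partially match those motif ratios.  The
generator reproduces that structure: each window is drawn i.i.d. from a
background base distribution, the center base is forced to A, and each motif
is then planted independently with a class-conditional probability at a
uniformly chosen offset that keeps the motif inside the window and never
overwrites the center.

Separability is fully controllable: identical insertion probabilities in the
two classes give an impossible problem, 1 vs 0 gives a nearly trivial one.
Planting overwrites background bases in place (no indels); when motifs
overlap, the last insertion wins.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .seqdata import Dataset, LabelledWindow, center_index

_BASES = np.array(list("ACGT"))
_BASE_TO_CODE = {b: i for i, b in enumerate("ACGT")}

#: Default planted motifs as (motif, insertion prob in positives, in negatives).
#: GAGG is the canonical 6mA-associated motif and carries the class signal;
#: AGG is mildly enriched; AG is common and near-uninformative, mimicking
#: negative sets sampled to match short-motif content.
DEFAULT_MOTIFS: tuple[tuple[str, float, float], ...] = (
    ("GAGG", 0.9, 0.1),
    ("AGG", 0.4, 0.2),
    ("AG", 0.5, 0.5),
)

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete, serializable description of one generated dataset."""

    n_positive: int
    n_negative: int
    window_length: int = 41
    motifs: tuple[tuple[str, float, float], ...] = DEFAULT_MOTIFS
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND
    seed: int = 0

    def validate(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("class counts must be non-negative")
        if self.window_length < 1:
            raise ValueError("window_length must be positive")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError(f"background frequencies must sum to 1, got {self.background}")
        if any(p < 0 for p in self.background):
            raise ValueError("background frequencies must be non-negative")
        for motif, p_pos, p_neg in self.motifs:
            if not motif or set(motif) - set("ACGT"):
                raise ValueError(f"motif must be a nonempty ACGT string, got {motif!r}")
            if len(motif) > self.window_length:
                raise ValueError(
                    f"motif {motif} (length {len(motif)}) exceeds window length "
                    f"{self.window_length}"
                )
            for p in (p_pos, p_neg):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"insertion probability {p} for {motif} outside [0, 1]")
            if not _admissible_offsets(motif, self.window_length):
                raise ValueError(
                    f"motif {motif} has no placement that avoids the center position"
                )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = json.load(fh)
        raw["motifs"] = tuple((m, float(pp), float(pn)) for m, pp, pn in raw["motifs"])
        raw["background"] = tuple(raw["background"])
        return cls(**raw)


def _admissible_offsets(motif: str, window_length: int) -> list[int]:
    """Offsets keeping the motif inside the window and clear of the center."""
    mid = center_index(window_length)
    k = len(motif)
    return [o for o in range(window_length - k + 1) if not (o <= mid < o + k)]


def generate(spec: SyntheticSpec) -> Dataset:
    """Generate ``n_positive + n_negative`` labelled windows per the spec.

    Deterministic given ``spec.seed``.  Positives come first, each class in
    generation order, with ids ``pos_<i>`` / ``neg_<i>``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mid = center_index(spec.window_length)
    offsets = {m: _admissible_offsets(m, spec.window_length) for m, _, _ in spec.motifs}
    motif_codes = {
        m: np.array([_BASE_TO_CODE[b] for b in m], dtype=np.int64) for m, _, _ in spec.motifs
    }

    windows: list[LabelledWindow] = []
    for label, count, prefix in ((1, spec.n_positive, "pos"), (0, spec.n_negative, "neg")):
        for i in range(count):
            codes = rng.choice(4, size=spec.window_length, p=spec.background)
            codes[mid] = 0  # force the central adenine
            for motif, p_pos, p_neg in spec.motifs:
                p = p_pos if label == 1 else p_neg
                if rng.random() < p:
                    admissible = offsets[motif]
                    off = admissible[rng.integers(len(admissible))]
                    codes[off : off + len(motif)] = motif_codes[motif]
            windows.append(
                LabelledWindow(
                    sequence="".join(_BASES[codes]), label=label, id=f"{prefix}_{i}"
                )
            )
    return Dataset(windows=windows, name="synthetic", window_length=spec.window_length)


def _contains(sequence: str, motif: str) -> bool:
    return motif in sequence


def spec_report(dataset: Dataset, motifs: list[str] | tuple[str, ...]) -> dict:
    """Fraction of windows containing each motif, per class.

    Returns ``{motif: {"positive": frac, "negative": frac}}``; a class absent
    from the dataset reports ``None`` for its fraction.
    """
    if len(dataset) == 0:
        raise ValueError("spec_report requires a nonempty dataset")
    report: dict[str, dict[str, float | None]] = {}
    pos = [w.sequence for w in dataset if w.label == 1]
    neg = [w.sequence for w in dataset if w.label == 0]
    for motif in motifs:
        report[motif] = {
            "positive": (sum(_contains(s, motif) for s in pos) / len(pos)) if pos else None,
            "negative": (sum(_contains(s, motif) for s in neg) / len(neg)) if neg else None,
        }
    return report
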