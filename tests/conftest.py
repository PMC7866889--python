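import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sixmapred.seqdata import Dataset, LabelledWindow

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

_BASES = np.array(list("ACGT"))


def random_window(rng: np.random.Generator, length: int = 41) -> str:
    codes = rng.integers(0, 4, length)
    codes[(length + 1) // 2 - 1] = 0
    return "".join(_BASES[codes])


def make_separable_dataset(
    n_per_class: int, rng: np.random.Generator, fixed_offset: int | None = None
) -> Dataset:
    """Fully separable toy set: every positive contains GAGG (optionally at a
    fixed offset), negatives are rejection-sampled to contain no GAGG at all."""
    windows = []
    for i in range(n_per_class):
        codes = rng.integers(0, 4, 41)
        codes[20] = 0
        if fixed_offset is None:
            admissible = [o for o in range(38) if not (o <= 20 < o + 4)]
            off = admissible[rng.integers(len(admissible))]
        else:
            off = fixed_offset
        codes[off : off + 4] = [2, 0, 2, 2]
        windows.append(LabelledWindow("".join(_BASES[codes]), 1, f"pos_{i}"))
    i = 0
    while i < n_per_class:
        seq = random_window(rng)
        if "GAGG" not in seq:
            windows.append(LabelledWindow(seq, 0, f"neg_{i}"))
            i += 1
    return Dataset(windows, name="separable")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def balanced_dataset(rng):
    """100 random windows, 50 per class."""
    windows = [
        LabelledWindow(random_window(rng), label, f"w{label}_{i}")
        for label in (1, 0)
        for i in range(50)
    ]
    return Dataset(windows, name="balanced100")
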