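import random

import pytest

from guidepop import PamSpec

#: The seven supported PAM classes with their default orientations.
PAM_PATTERNS = ["NGG", "NNGRRT", "TTTV", "NNNNGATT", "TTTN", "NCC", "NNAGAAW"]


@pytest.fixture
def ngg() -> PamSpec:
    return PamSpec("NGG")


def random_dna(rng: random.Random, length: int, n_rate: float = 0.0) -> str:
    bases = "ACGT"
    return "".join(
        "N" if n_rate and rng.random() < n_rate else rng.choice(bases)
        for _ in range(length)
    )
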