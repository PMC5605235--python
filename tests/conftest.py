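import numpy as np
import pytest

from imotifkit import MotifRule, SequenceRecord


@pytest.fixture
def default_rule() -> MotifRule:
    return MotifRule()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def random_dna(rng: np.random.Generator, length: int,
               probs=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list("ACGT"), size=length, p=list(probs)))


@pytest.fixture
def c_rich_sequences(rng) -> list[SequenceRecord]:
    """Cytosine-skewed random sequences so rule matches actually occur."""
    probs = (0.12, 0.60, 0.12, 0.16)
    return [
        SequenceRecord(id=f"s{i}", sequence=random_dna(rng, int(rng.integers(30, 201)), probs))
        for i in range(250)
    ]
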