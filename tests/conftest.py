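import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kmerbg import SequenceRecord, SequenceSet, random_sequences

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_set(*texts: str, label: str = "test") -> SequenceSet:
    return SequenceSet(
        records=[SequenceRecord(id=f"s{i}", residues=t) for i, t in enumerate(texts)],
        label=label,
    )


@pytest.fixture(scope="session")
def uniform_1mb() -> SequenceSet:
    """1 Mb iid uniform random sequence (fixed seed)."""
    return random_sequences(1, 1_000_000, 0.5, seed=42, label="uniform1mb")


@pytest.fixture(scope="session")
def random_10kb() -> SequenceSet:
    """10 kb iid uniform random sequence (fixed seed)."""
    return random_sequences(1, 10_000, 0.5, seed=7, label="random10kb")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
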