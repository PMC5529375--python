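import pytest

from mitochar import AnnotatedGenome, FeatureRecord, SyntheticSpec, generate_genome
from mitochar import reference_data as ref


@pytest.fixture(scope="session")
def ar_genome():
    """Published hawk-moth annotation over a placeholder sequence."""
    return ref.reference_genome("A_rubiginosa")


@pytest.fixture(scope="session")
def rm_genome():
    """Published silk-moth-relative annotation over a placeholder sequence."""
    return ref.reference_genome("R_menciana")


@pytest.fixture(scope="session")
def synthetic_pair():
    """One deterministic synthetic genome with its recorded ground truth."""
    return generate_genome(SyntheticSpec(seed=1))


@pytest.fixture()
def toy_genome():
    """A 30-bp circular genome with three abutting features."""
    seq = "ATGAAATAAGGGCCCTTTAAACCCGGGATT"
    feats = [
        FeatureRecord("a", "other", "F", 1, 10),
        FeatureRecord("b", "other", "R", 11, 20),
        FeatureRecord("c", "other", "F", 21, 30),
    ]
    return AnnotatedGenome("toy", seq, feats)
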