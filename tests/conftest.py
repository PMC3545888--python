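import numpy as np
import pytest

from baculokit.genome_io import CircularGenome, load_reference_annotation
from baculokit.synthetic_data import GeneratorConfig, generate_annotated_genome


@pytest.fixture(scope="session")
def reference_ann():
    """The packaged HearMNPV annotation table (162 ORFs, 4 hrs)."""
    return load_reference_annotation()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One default synthetic genome with its ground truth (seed 7)."""
    return generate_annotated_genome(GeneratorConfig(seed=7))


def random_seq(rng: np.random.Generator, n: int, p=None) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_genome(seq: str, circular: bool = True,
                gid: str = "test") -> CircularGenome:
    return CircularGenome(gid, seq, circular=circular)
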