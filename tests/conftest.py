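import numpy as np
import pytest

from cracflow.annotation import AnnotatedGenome, Feature
from cracflow.synthetic import SyntheticGenomeSpec, generate_genome

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_seq(n: int, seed: int = 7) -> str:
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


@pytest.fixture(scope="session")
def toy_genome() -> AnnotatedGenome:
    """Handcrafted single-chromosome genome exercising every edge case:

    a 2-exon + strand mRNA with a 300-nt intron, a snoRNA nested inside it
    (sense), a 2-exon - strand mRNA, a tRNA (exclusion class), a plain mRNA
    for antisense tests and a - strand SUT.
    """
    features = [
        Feature("mRNA_A", "chrI", 1000, 2600, "+", "mRNA",
                ((1000, 1500), (1800, 2600))),
        Feature("sno_A", "chrI", 2000, 2100, "+", "snoRNA"),
        Feature("mRNA_B", "chrI", 4000, 5200, "-", "mRNA",
                ((4000, 4400), (4700, 5200))),
        Feature("tRNA_A", "chrI", 6000, 6080, "+", "tRNA"),
        Feature("mRNA_C", "chrI", 7000, 7500, "+", "mRNA"),
        Feature("SUT_A", "chrI", 8000, 8400, "-", "SUT"),
    ]
    return AnnotatedGenome({"chrI": random_seq(10_000)}, features)


@pytest.fixture(scope="session")
def small_genome() -> AnnotatedGenome:
    """A generated miniature genome shared across tests (seed-fixed)."""
    return generate_genome(SyntheticGenomeSpec(seed=11))
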