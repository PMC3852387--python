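import numpy as np
import pytest

from spotwing.io import SeqRecord
from spotwing.simulate import simulate_genome
from spotwing.te import TELibrary


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="session")
def small_genome():
    """A 200-kb genome with 20 multi-exon genes (seed 11)."""
    return simulate_genome(11, 200_000, 20)


@pytest.fixture(scope="session")
def te_library():
    """Eight random reference elements, alternating DNA/RNA classes."""
    rng = np.random.default_rng(90013)
    elems = [SeqRecord(id=f"TE{i}", seq=random_seq(rng, int(rng.integers(500, 2500))))
             for i in range(8)]
    classes = {e.id: ("DNA" if i % 2 == 0 else "RNA")
               for i, e in enumerate(elems)}
    return TELibrary(elements=elems, class_map=classes)
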