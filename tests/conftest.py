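import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from mitobe import CircularGenome, plant_motif, random_circular_genome


@pytest.fixture
def tiny_genome() -> CircularGenome:
    return CircularGenome(name="tiny", sequence="ACGT")


@pytest.fixture
def planted_genome() -> CircularGenome:
    """300-bp random genome with one GATC planted at duplex position 120."""
    g = random_circular_genome(300, gc=0.5, seed=11)
    return plant_motif(g, "GATC", 120)


@pytest.fixture
def random_genomes() -> list[CircularGenome]:
    return [random_circular_genome(200 + 37 * i, gc=0.3 + 0.02 * i, seed=i)
            for i in range(12)]
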