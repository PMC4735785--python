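import pytest

from capfuse import io
from capfuse.rearrange import GenomeModel
from capfuse.simulate import make_toy_genome


@pytest.fixture(scope="session")
def junction_table():
    """Packaged 26-patient breakpoint table."""
    return io.read_junction_table()


@pytest.fixture(scope="session")
def patient_table():
    return io.read_patient_table()


@pytest.fixture(scope="session")
def relapse_table():
    return io.read_relapse_table()


@pytest.fixture()
def toy_genome_xy():
    """Coordinate-only diploid toy genome from the derivative examples."""
    return GenomeModel(lengths={"chrX": 1000, "chrY": 1000},
                       centromeres={"chrX": (600, 650), "chrY": (100, 150)})


@pytest.fixture(scope="session")
def small_seq_genome():
    """4 kbp two-chromosome genome with sequences, for resolution tests."""
    return make_toy_genome([("cA", 4000, (100, 150)), ("cB", 4000, (3800, 3850))],
                           seed=11)
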