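import pytest

from shuffleplan.codon_space import default_usage_table
from shuffleplan.energetics import load_nn_table
from shuffleplan.oracle_and_fixtures import make_toy


@pytest.fixture(scope="session")
def usage():
    return default_usage_table()


@pytest.fixture(scope="session")
def nn_table():
    return load_nn_table()


def build_toy_suite(n_instances: int = 100):
    """Seeded toy instances spanning n in [2, 5], m in [0, 2], with and
    without gap columns; small enough for exhaustive enumeration."""
    suite = []
    for seed in range(n_instances):
        n = 2 + seed % 4
        m = seed % 3
        inst = make_toy(
            seed,
            n=n,
            m=m,
            gap_rate=0.15 if seed % 5 == 0 else 0.0,
            max_options=3 if n <= 4 else 2,
        )
        suite.append(inst)
    return suite


@pytest.fixture(scope="session")
def toy_suite():
    return build_toy_suite(100)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(name: str, records: dict) -> str:
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return str(path)

    return _write
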