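import pytest

from convergene import GeneSet, GeneUniverse, gen_universe


@pytest.fixture
def small_universe() -> GeneUniverse:
    return gen_universe(1000, seed=0)


@pytest.fixture
def write_gene_file(tmp_path):
    """Write raw lines to a temp gene-list file and return its path."""

    def _write(lines, name="genes.txt"):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return p

    return _write


def make_set(name: str, symbols) -> GeneSet:
    return GeneSet(name=name, members=frozenset(symbols))


@pytest.fixture
def abc_sets():
    a = make_set("A", {"G1", "G2", "G3", "G4"})
    b = make_set("B", {"G3", "G4", "G5"})
    c = make_set("C", {"G4", "G5", "G6", "G7"})
    return a, b, c
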