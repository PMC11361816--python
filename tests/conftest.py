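import pytest

from ddikit.synthetic_data import (
    BenchmarkConfig,
    FlatConfig,
    gen_3did_flat,
    gen_benchmark_table,
)

# handcrafted flat fixture: 3 type blocks, 5 interface lines, with the first
# interface of the first block carrying 17 contact lines
FLAT_FIXTURE_LINES = []


def _interface(pdb, loc_a, loc_b, score, zscore, contacts):
    lines = [f"#=3D\t{pdb}\t{loc_a}\t{loc_b}\t{score}\t{zscore}"]
    lines += [f"{a}\t{b}" for a, b in contacts]
    return lines


_c5 = [(str(10 + i), str(50 + i)) for i in range(5)]
_c17 = [(str(100 + i), str(200 + i)) for i in range(17)]

FLAT_FIXTURE_LINES += ["#=ID\tdom1\tdom2\t(PF00001.5@Pfam\tPF00002.3@Pfam)"]
FLAT_FIXTURE_LINES += _interface("1abc", "A:1-90", "B:10-100", 7.5, 3.1, _c17)
FLAT_FIXTURE_LINES += _interface("2def", "A:1-90", "A:120-200", 4.0, 1.2, _c5)
FLAT_FIXTURE_LINES += ["//"]
FLAT_FIXTURE_LINES += ["#=ID\tdom3\tdom4\t(PF00004.1@Pfam\tPF00003.1@Pfam)"]
FLAT_FIXTURE_LINES += _interface("3ghi", "C:1-50", "D:1-60", 9.0, 5.0, _c5)
FLAT_FIXTURE_LINES += _interface("3ghi", "E:1-50", "F:1-60", 2.0, 0.5, _c5)
FLAT_FIXTURE_LINES += ["//"]
FLAT_FIXTURE_LINES += ["#=ID\tdom5\tdom5\t(PF00005.2@Pfam\tPF00005.2@Pfam)"]
FLAT_FIXTURE_LINES += _interface("4jkl", "A:1-80", "B:1-80", 3.3, 2.2, _c5)
FLAT_FIXTURE_LINES += ["//"]

FLAT_FIXTURE = "\n".join(FLAT_FIXTURE_LINES) + "\n"


@pytest.fixture
def flat_path(tmp_path):
    path = tmp_path / "flat.txt"
    path.write_text(FLAT_FIXTURE)
    return path


@pytest.fixture
def generated_flat(tmp_path):
    """Seeded generator output: (path, truth table, chain map)."""
    text, truth, cmap = gen_3did_flat(
        FlatConfig(seed=11, n_intrachain=4, n_homoprotein=5, n_hetero=6)
    )
    path = tmp_path / "gen_flat.txt"
    path.write_text(text)
    return path, truth, cmap


@pytest.fixture(scope="session")
def benchmark_table():
    """Default synthetic stand-in for the curated benchmark: 80 labeled rows."""
    table, truth = gen_benchmark_table(BenchmarkConfig(seed=7))
    return table, truth
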