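import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def write_tsv(tmp_path):
    """Write tab-separated lines to a temp file and return its path."""

    def _write(name, rows, header=None):
        path = tmp_path / name
        with open(path, "w", encoding="utf-8") as fh:
            if header is not None:
                fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(c) for c in row) + "\n")
        return path

    return _write


@pytest.fixture
def small_scenario():
    """A fast, fully featured synthetic scenario for integration tests."""
    from mirpath.synthetic import SyntheticScenario

    return SyntheticScenario(
        n_genes=600,
        n_pathways=10,
        pathway_size_range=(10, 20),
        n_mirnas=50,
        target_size_range=(20, 40),
        seed=7,
    )
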