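import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from dppscan import OrthologAlignment


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def tsv_file(tmp_path):
    def _write(text, name="table.tsv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def small_alignment():
    """Four orthologs of a motif-bearing N-terminus, one with gaps."""
    return OrthologAlignment(
        name="demo",
        rows=(
            ("human", "MAPSVPAA"),
            ("mouse", "MAPSVPAA"),
            ("frog", "MAPNVP-A"),
            ("fish", "MAPTLPAA"),
        ),
    )
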