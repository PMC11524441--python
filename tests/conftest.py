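import pandas as pd
import pytest
from hypothesis import settings

from oasig import DETable

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_de_table(rows, dataset_id="test", species="Mus musculus") -> DETable:
    """Build a DETable from (gene, log2fc, pvalue, fdr) tuples."""
    frame = pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue", "fdr"])
    return DETable(dataset_id=dataset_id, species=species, frame=frame)


@pytest.fixture
def de_table_5genes() -> DETable:
    """Five genes spanning the significance boundary cases."""
    return make_de_table(
        [
            ("A", 1.0, 0.001, 0.01),
            ("B", 0.5, 0.001, 0.01),
            ("C", -0.7, 0.01, 0.04),
            ("D", 2.0, 0.02, 0.06),
            ("E", -3.0, 0.01, 0.05),
        ]
    )


@pytest.fixture
def tsv_writer(tmp_path):
    """Write tab-separated text content to a temp file and return its path."""

    def write(name: str, text: str):
        p = tmp_path / name
        p.write_text(text, encoding="utf-8")
        return p

    return write
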