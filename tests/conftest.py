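import numpy as np
import pandas as pd
import pytest

from mrclustmed.gwas_io import CANONICAL_COLUMNS


def make_stats(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical summary-statistics table from sparse row dicts."""
    # p matches the default beta/se (Z = 10) so no consistency warning fires
    defaults = {"chr": "1", "pos": 1000, "ea": "A", "oa": "G", "eaf": 0.3,
                "beta": 0.1, "se": 0.01, "p": 1.524e-23, "n": 100_000}
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults, rsid=f"rs{i + 1}", pos=1000 + i * 2_000_000)
        r.update(row)
        full.append(r)
    return pd.DataFrame(full)[CANONICAL_COLUMNS]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stats_file(tmp_path):
    """Write rows to a temporary canonical TSV and return the path."""

    def _write(rows: list[dict] | pd.DataFrame, name: str = "stats.tsv"):
        df = rows if isinstance(rows, pd.DataFrame) else make_stats(rows)
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return _write
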