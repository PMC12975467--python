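import numpy as np
import pytest

import taxometrics as tx


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def taxonic_spec():
    """The standard recovery-test condition: k=3, n=600, d=2, p=0.25, r=0.1."""
    return tx.SyntheticSpec(
        "taxonic", n=600, k=3, base_rate=0.25, separation=2.0, within_r=0.1
    )


@pytest.fixture
def taxonic_matrix(taxonic_spec):
    matrix, flags = tx.simulate_taxonic(taxonic_spec, 11)
    return matrix, flags


@pytest.fixture
def csv_file(tmp_path):
    """Write a small delimited table and return its path."""

    def _write(text, name="data.csv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
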