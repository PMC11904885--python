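import numpy as np
import pandas as pd
import pytest

import mhcload as m

# study-condition-scale objects are expensive; build once per session


@pytest.fixture(scope="session")
def schemes():
    return m.load_builtin_schemes()


@pytest.fixture(scope="session")
def featurizer():
    return m.CTDFeaturizer(warn_length_range=None).fit()


@pytest.fixture(scope="session")
def small_table():
    """A small synthetic assay table + ground truth shared across tests."""
    table, truth = m.generate_assay_table(n_epitopes=250, seed=42)
    return table, truth


@pytest.fixture(scope="session")
def small_dataset(small_table):
    table, _ = small_table
    records, n_malformed = _records_from_table(table)
    return m.curate(records, min_per_class=50, n_malformed=n_malformed)


def _records_from_table(table: pd.DataFrame):
    """Route a generated table through the real reader via a temp file."""
    import io

    buf = io.StringIO()
    table.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        fh.write(buf.getvalue())
        path = fh.name
    try:
        return m.read_assay_table(path)
    finally:
        os.unlink(path)


@pytest.fixture(scope="session")
def tiny_config():
    """A deliberately small training configuration for fast registry tests."""
    return m.TrainingConfig(
        alpha_grid=[0.5],
        repeats=2,
        inner_folds=6,
        n_lambda=8,
        lambda_min_ratio=1e-2,
        qc_cutoffs=(1, 2),
        tol=1e-5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_registry(small_dataset, tiny_config):
    return m.build_registry(small_dataset, tiny_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240514)
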