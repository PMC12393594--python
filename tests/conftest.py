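"""Shared fixtures: the default synthetic dataset processed once per
session (generation -> QC -> normalization -> clustering)."""

import warnings

import numpy as np
import pytest

from stcelldyn import clustering, preprocess
from stcelldyn.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def processed(default_dataset):
    """(dataset, X normalized, gene_names, cells, truth types) after QC."""
    ds = default_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X, gkeep, ckeep, report = preprocess.run_qc(
            ds.counts, ds.genes, ds.cells, fov_scale=0.1)
    neg = ds.genes["is_negative_probe"].to_numpy()
    gene_names = list(ds.genes.index[gkeep][~neg[gkeep]])
    cells = ds.cells.iloc[ckeep]
    truth = ds.truth.cell_type_of_cell[ckeep]
    return ds, X, gene_names, cells, truth, report, ckeep


@pytest.fixture(scope="session")
def clustered(processed):
    ds, X, gene_names, cells, truth, report, ckeep = processed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        E, assign = clustering.cluster_all(X, cells, seed=0)
    return E, assign


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
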