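"""Shared fixtures: small on-disk inputs and simulated experiments."""

from __future__ import annotations

import textwrap
from pathlib import Path

import numpy as np
import pytest

import receptormine as rm


@pytest.fixture
def series_matrix_text() -> str:
    """Minimal GEO series-matrix: 3 probes x 2 samples, values 1..6."""
    return textwrap.dedent(
        """\
        !Series_geo_accession\t"GSE100"
        !Sample_geo_accession\t"GSM1"\t"GSM2"
        !Sample_platform_id\t"GPL1"\t"GPL1"
        !Sample_channel_count\t"1"\t"1"
        !series_matrix_table_begin
        "ID_REF"\t"GSM1"\t"GSM2"
        p1\t1\t2
        p2\t3\t4
        p3\t5\t6
        !series_matrix_table_end
        """
    )


@pytest.fixture
def series_matrix_file(tmp_path: Path, series_matrix_text: str) -> Path:
    path = tmp_path / "GSE100_series_matrix.txt"
    path.write_text(series_matrix_text)
    return path


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated experiment (seed 1), shared across tests."""
    return rm.simulate_experiment(rm.SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast experiment for pipeline-level tests."""
    config = rm.SimConfig(
        seed=7,
        n_genes=40,
        probesets_per_gene=(2, 3),
        probes_per_probeset=(8, 10),
        categories={"neuron": 4, "glia": 4},
    )
    return rm.simulate_experiment(config)


@pytest.fixture(scope="session")
def small_normalized(small_sim):
    experiment, truth, annotation = small_sim
    probesets = rm.rma(experiment)
    genes = rm.collapse_to_genes(probesets, experiment.chip)
    return probesets, genes


def make_expression(values: np.ndarray, categories: list[str], prefix: str = "g"):
    """Wrap a raw array as a gene-level ExpressionMatrix with categories."""
    values = np.asarray(values, dtype=float)
    samples = [
        rm.SampleMeta(f"s{j}", series_id=f"se{j % 2}", category=c)
        for j, c in enumerate(categories)
    ]
    ids = [f"{prefix}{i}" for i in range(values.shape[0])]
    return rm.ExpressionMatrix(values, ids, samples, level="gene")
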