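import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from funcfly.containers import TIME_LABELS, GoDag
from funcfly.synthetic_data import (
    BenchmarkConfig,
    PlantedTermSpec,
    generate_benchmark,
    worked_example_gene,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_gene_frame(values, lengths, gene_id="geneX", protein_ids=None):
    """Build a one-gene expression frame from a (transcripts x 30) array."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if protein_ids is None:
        protein_ids = [f"{gene_id}.p{i + 1}" for i in range(n)]
    rows = []
    for i in range(n):
        rows.append(
            [f"{gene_id}.t{i + 1}", gene_id, protein_ids[i], int(lengths[i]),
             *values[i]]
        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "protein_id", "isoform_length",
                 *TIME_LABELS],
    )


@pytest.fixture
def worked_gene():
    return worked_example_gene()


@pytest.fixture(scope="session")
def tiny_dag():
    """10-term DAG spanning the three namespaces, with a part_of edge."""
    terms = [
        ("GO:0000001", "bp root", "BP"),
        ("GO:0000002", "bp mid a", "BP"),
        ("GO:0000003", "bp mid b", "BP"),
        ("GO:0000004", "bp leaf a", "BP"),
        ("GO:0000005", "bp leaf b", "BP"),
        ("GO:0000006", "bp leaf c", "BP"),
        ("GO:0000007", "mf root", "MF"),
        ("GO:0000008", "mf leaf", "MF"),
        ("GO:0000009", "cc root", "CC"),
        ("GO:0000010", "cc leaf", "CC"),
    ]
    edges = [
        ("GO:0000002", "GO:0000001", "is_a"),
        ("GO:0000003", "GO:0000001", "is_a"),
        ("GO:0000004", "GO:0000002", "is_a"),
        ("GO:0000005", "GO:0000002", "part_of"),
        ("GO:0000005", "GO:0000003", "is_a"),   # diamond: two paths to root
        ("GO:0000006", "GO:0000003", "is_a"),
        ("GO:0000008", "GO:0000007", "is_a"),
        ("GO:0000010", "GO:0000009", "part_of"),
    ]
    return GoDag.from_edges(terms, edges)


@pytest.fixture(scope="session")
def small_benchmark():
    """One expression-driven, one sequence-driven and one null term over
    120 genes; shared by several test modules."""
    config = BenchmarkConfig(
        n_genes=120,
        n_seq_features=40,
        terms=(
            PlantedTermSpec(namespace="BP", driver="expression", n_positives=30),
            PlantedTermSpec(namespace="MF", driver="sequence", n_positives=30,
                            n_seq_affected=6),
            PlantedTermSpec(namespace="CC", driver="null", n_positives=25),
        ),
        seed=7,
    )
    return generate_benchmark(config)
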