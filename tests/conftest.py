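import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from srnatlas.model import CountMatrix, SampleMeta

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, length: int = 20) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_matrix(
    columns: dict[str, list[int]],
    sources: dict[str, tuple[str, str, int]] | None = None,
    sequences: list[str] | None = None,
    biotypes: list[str] | None = None,
    genes: list[str] | None = None,
) -> CountMatrix:
    """Build a small valid CountMatrix from per-sample count lists.

    ``sources`` maps sample_id -> (source, source_class, replicate);
    defaults to one tissue with consecutive replicates.
    """
    n_rows = len(next(iter(columns.values())))
    rng = np.random.default_rng(abs(hash(tuple(sorted(columns)))) % 2**31)
    if sequences is None:
        sequences = []
        while len(sequences) < n_rows:
            s = random_sequence(rng)
            if s not in sequences:
                sequences.append(s)
    if biotypes is None:
        biotypes = ["miRNA"] * n_rows
    if genes is None:
        genes = [f"gene-{i}" for i in range(n_rows)]
    counts = pd.DataFrame(columns, index=pd.Index(sequences, name="sequence"))
    row_meta = pd.DataFrame(
        {"biotype": biotypes, "parent_gene": genes}, index=counts.index
    )
    if sources is None:
        samples = [
            SampleMeta(sid, "TISSUE_A", "tissue", i + 1)
            for i, sid in enumerate(columns)
        ]
    else:
        samples = [
            SampleMeta(sid, *sources[sid]) for sid in columns
        ]
    return CountMatrix(counts, row_meta, samples)


def random_matrix(
    rng: np.random.Generator,
    n_rows: int,
    n_cols: int,
    source_class: str = "tissue",
    positive: bool = False,
    max_count: int = 1000,
) -> CountMatrix:
    low = 1 if positive else 0
    counts = rng.integers(low, max_count, size=(n_rows, n_cols))
    if not positive and n_rows > 1:
        counts[0] = rng.integers(1, max_count, size=n_cols)  # keep a reference row
    cols = {f"s{j}": counts[:, j].tolist() for j in range(n_cols)}
    sources = {
        f"s{j}": (f"SRC_{j % max(1, n_cols // 2)}", source_class, j + 1)
        for j in range(n_cols)
    }
    genes = [f"gene-{i % max(1, n_rows // 2)}" for i in range(n_rows)]
    return make_matrix(cols, sources=sources, genes=genes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix() -> CountMatrix:
    return make_matrix(
        {"a1": [30, 5, 0], "a2": [28, 7, 1], "a3": [26, 40, 2]},
        sources={
            "a1": ("TISSUE_A", "tissue", 1),
            "a2": ("TISSUE_A", "tissue", 2),
            "a3": ("TISSUE_A", "tissue", 3),
        },
    )
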