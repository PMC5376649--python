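import numpy as np
import pandas as pd
import pytest

from clonescreen import (
    CountMatrix,
    LibraryAnnotation,
    SampleSheet,
)
from clonescreen.simulate import SimConfig, simulate_screen

BASES = "ACGT"


def make_barcode(i: int) -> str:
    """Deterministic distinct 18-mer for index i (base-4 expansion)."""
    digits = []
    for _ in range(18):
        digits.append(BASES[i % 4])
        i //= 4
    return "".join(digits)


def make_library(genes_to_n: dict[str, int]) -> LibraryAnnotation:
    rows, i = [], 0
    for gene, n in genes_to_n.items():
        for j in range(1, n + 1):
            rows.append((f"{gene}_sh{j}", gene, make_barcode(i)))
            i += 1
    return LibraryAnnotation(
        pd.DataFrame(rows, columns=["shrna_id", "gene_symbol", "barcode"])
    )


@pytest.fixture
def tiny_library() -> LibraryAnnotation:
    """Two genes with the 5/6 hairpins-per-gene library design."""
    return make_library({"G1": 5, "G2": 6})


@pytest.fixture
def tiny_samples() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s_t0_r1", "s_t0_r2", "s_t14_r1", "s_t14_r2"],
                "screen": ["NHK"] * 4,
                "timepoint": ["t0", "t0", "t14", "t14"],
                "replicate": [1, 2, 1, 2],
            }
        )
    )


@pytest.fixture
def tiny_counts(tiny_library, tiny_samples) -> CountMatrix:
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(50, 150, size=(tiny_library.n_shrnas, 4)),
        index=pd.Index(tiny_library.shrna_ids, name="shrna_id"),
        columns=tiny_samples.sample_ids,
    )
    return CountMatrix(counts, tiny_samples)


@pytest.fixture(scope="session")
def small_sim():
    """A small planted screen shared across tests (deterministic)."""
    cfg = SimConfig(n_genes=150, reads_per_sample=300_000, seed=5)
    return cfg, simulate_screen(cfg)
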