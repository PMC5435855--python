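import numpy as np
import pandas as pd
import pytest

from srna_dekit.core import (
    ExpressionMatrix,
    ReadLibrary,
    SampleHierarchy,
    build_expression_matrix,
)

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def random_library(rng: np.random.Generator, replicate_id: str, n: int = 30) -> ReadLibrary:
    counts = {}
    while len(counts) < n:
        seq = random_sequence(rng, int(rng.integers(18, 31)))
        counts[seq] = int(rng.integers(1, 200))
    return ReadLibrary(replicate_id, counts)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def hierarchy_2x2() -> SampleHierarchy:
    return SampleHierarchy([("ctrl", ["c1", "c2"]), ("treat", ["t1", "t2"])])


@pytest.fixture
def paired_matrix(hierarchy_2x2) -> ExpressionMatrix:
    """Small matrix where replicate 2 of each treatment is exactly 2x replicate 1."""
    seqs = ["ACGTACGTACGTACGTACGTA", "CCGTACGTACGTACGTACGTA",
            "GCGTACGTACGTACGTACGTA", "TCGTACGTACGTACGTACGTA"]
    vals = pd.DataFrame(
        {
            "c1": [10, 20, 30, 40],
            "c2": [20, 40, 60, 80],
            "t1": [5, 15, 25, 35],
            "t2": [10, 30, 50, 70],
        },
        index=pd.Index(seqs, name="sequence"),
    )
    return ExpressionMatrix(vals, hierarchy_2x2)


@pytest.fixture
def random_matrix(rng, hierarchy_2x2) -> ExpressionMatrix:
    libs = [random_library(rng, rid, 40) for rid in hierarchy_2x2.replicate_ids]
    return build_expression_matrix(libs, hierarchy_2x2)
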