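import numpy as np
import pytest

from speccount import (
    CountMatrix,
    SampleInfo,
    fit_effective_totals,
    load_table2,
)


@pytest.fixture(scope="session")
def table2_rows():
    return load_table2()


@pytest.fixture(scope="session")
def calibrated(table2_rows):
    return fit_effective_totals(table2_rows)


@pytest.fixture
def small_matrix():
    """2 proteins x 3 runs, one group, one patient in triplicate."""
    samples = [
        SampleInfo(f"S{i}", "LCNEC", "p1", i) for i in (1, 2, 3)
    ]
    return CountMatrix(
        protein_ids=["P1", "P2"],
        samples=samples,
        counts=np.array([[2, 3, 4], [0, 0, 0]]),
    )


def make_matrix(rng, n_proteins=50, groups=("A", "B", "C"), patients=3, reps=3):
    """Random valid matrix for round-trip and pooling tests."""
    samples = []
    for g in groups:
        for p in range(1, patients + 1):
            for r in range(1, reps + 1):
                samples.append(SampleInfo(f"{g}{p}r{r}", g, f"{g}{p}", r))
    counts = rng.poisson(3.0, size=(n_proteins, len(samples)))
    return CountMatrix(
        protein_ids=[f"P{i:04d}" for i in range(n_proteins)],
        samples=samples,
        counts=counts,
    )
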