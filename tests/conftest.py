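import numpy as np
import pandas as pd
import pytest

from refstab import (
    CqMatrix,
    EfficiencyTable,
    SimConfig,
    simulate_matrix,
)


@pytest.fixture
def toy_quantities() -> pd.DataFrame:
    """3 genes x 4 samples relative quantities with known geNorm arithmetic.

    A and B halve in lockstep; C is constant, so log2(A/C) runs 0,-1,-2,-3
    with SD 1.2910 and the A-B ratio is constant (SD 0).
    """
    return pd.DataFrame(
        {
            "s1": [1.0, 1.0, 1.0],
            "s2": [0.5, 0.5, 1.0],
            "s3": [0.25, 0.25, 1.0],
            "s4": [0.125, 0.125, 1.0],
        },
        index=["A", "B", "C"],
    )


@pytest.fixture
def unit_efficiency():
    """E = 100% for five generic genes: the corrected Cq equals raw Cq."""

    def make(genes):
        return EfficiencyTable.from_percent({g: 100.0 for g in genes})

    return make


@pytest.fixture
def small_matrix() -> CqMatrix:
    """A small deterministic collapsed Cq matrix for plumbing tests."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{j}" for j in range(10)]
    values = 25.0 + rng.normal(0, 1.0, size=(6, 10))
    return CqMatrix(pd.DataFrame(values, index=genes, columns=samples))


@pytest.fixture
def default_sim() -> tuple[CqMatrix, object, EfficiencyTable]:
    """One default-design synthetic dataset plus its efficiency table."""
    from refstab import efficiency_table

    cfg = SimConfig.paper_design(seed=11)
    matrix, truth = simulate_matrix(cfg)
    return matrix, truth, efficiency_table(cfg)


def random_cq_matrix(rng: np.random.Generator, k: int = 6, n: int = 10) -> CqMatrix:
    genes = [f"g{i}" for i in range(k)]
    samples = [f"s{j}" for j in range(n)]
    values = rng.uniform(18.0, 32.0, size=(k, n))
    return CqMatrix(pd.DataFrame(values, index=genes, columns=samples))
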