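import numpy as np
import pandas as pd
import pytest

from cryodiff import (
    CountMatrix,
    ExpressionMatrix,
    PlantedSet,
    SampleSheet,
    SimConfig,
    simulate_counts,
)


@pytest.fixture
def toy_counts() -> CountMatrix:
    """Three genes, one sample: counts (10, 20, 30), lengths (1000, 2000, 500)."""
    counts = pd.DataFrame({"s1": [10, 20, 30]}, index=["g1", "g2", "g3"])
    lengths = pd.Series([1000.0, 2000.0, 500.0], index=["g1", "g2", "g3"])
    return CountMatrix(counts, lengths)


@pytest.fixture
def two_by_two():
    """Minimal 2-vs-2 single-day dataset: TPM matrix + sample sheet."""
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample": ["a1", "a2", "b1", "b2"],
                "day": [8, 8, 8, 8],
                "condition": ["FRSH", "FRSH", "CRYO", "CRYO"],
                "pair": ["p1", "p2", "p1", "p2"],
            }
        )
    )

    def make(values: np.ndarray, genes=None) -> ExpressionMatrix:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        genes = genes or [f"g{i}" for i in range(values.shape[0])]
        return ExpressionMatrix(
            pd.DataFrame(values, index=genes, columns=["a1", "a2", "b1", "b2"]),
            unit="TPM",
        )

    return sheet, make


@pytest.fixture(scope="session")
def planted_simulation():
    """Small planted-effect dataset shared across recovery-style tests."""
    cfg = SimConfig(
        n_genes=600,
        nb_dispersion=0.05,
        mean_library_size=2e6,
        planted_down_sets=(PlantedSet("oxphos_like", 25, -2.0),),
        planted_up_sets=(PlantedSet("histone_like", 20, 2.0),),
        seed=42,
    )
    counts, sheet, truth = simulate_counts(cfg)
    return cfg, counts, sheet, truth
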