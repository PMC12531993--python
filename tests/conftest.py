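import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from multiomecnv.genome_bins import BinSet, ChromArmTable


@pytest.fixture(scope="session")
def toy_arms() -> ChromArmTable:
    """Two 10-Mb chromosomes: p 0-4 Mb, centromere 4-5 Mb, q 5-10 Mb."""
    return ChromArmTable(
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr2"],
                "p_start": [0, 0],
                "p_end": [4_000_000, 4_000_000],
                "q_start": [5_000_000, 5_000_000],
                "q_end": [10_000_000, 10_000_000],
                "length": [10_000_000, 10_000_000],
            }
        )
    )


@pytest.fixture(scope="session")
def toy_bins() -> BinSet:
    """Five 200-kb bins on chr1 plus two on chr2."""
    rows = [("chr1", i * 200_000, (i + 1) * 200_000) for i in range(5)]
    rows += [("chr2", 0, 200_000), ("chr2", 200_000, 400_000)]
    return BinSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


@pytest.fixture(scope="session")
def small_sample():
    """One small simulated multiome sample shared across integration tests."""
    from multiomecnv.synthetic_data import (
        CloneSpec,
        EventSpec,
        SimConfig,
        sim_genome,
        simulate_sample,
    )

    arms = sim_genome(3)
    events = (
        EventSpec("chr1", 30_000_000, 60_000_000, 1, 1),  # q-arm deletion
        EventSpec("chr2", 0, 27_000_000, 2, 2),  # p-arm CNLoH
        EventSpec("chr3", 30_000_000, 60_000_000, 3, 2),  # q-arm amplification
    )
    config = SimConfig(
        arms=arms,
        clones=(CloneSpec("normal", 0.3), CloneSpec("tumor", 0.7, events)),
        n_cells={"RNA": 120, "ATAC": 120},
        n_ref_cells={"RNA": 150, "ATAC": 150},
        seed=7,
    )
    return simulate_sample(config)
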