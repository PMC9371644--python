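import numpy as np
import pytest

from tadshift.genome_io import GenomeLayout, make_bin_table
from tadshift.simulate import (
    BoundarySpec,
    GeneSpec,
    SimulationConfig,
    demo_config,
)


@pytest.fixture(scope="session")
def small_layout():
    return GenomeLayout(
        ("chr1", "chr2"),
        {"chr1": 4_000_000, "chr2": 3_000_000},
        centromeres={"chr1": (1_900_000, 2_100_000)},
    )


@pytest.fixture(scope="session")
def demo():
    return demo_config(seed=1)


@pytest.fixture(scope="session")
def small_sim(small_layout):
    """A miniature two-condition experiment for fast pipeline tests."""
    boundaries = (
        BoundarySpec("chr1", 800_000, 0.2, hds=True),
        BoundarySpec("chr1", 3_200_000, 0.3, hds=False),
        BoundarySpec("chr2", 1_000_000, 0.25, hds=True),
        BoundarySpec("chr2", 2_000_000, 0.4, hds=False),
    )
    genes = tuple(
        GeneSpec(
            f"g{i}", "chr1", 100_000 + 300_000 * i, 120_000 + 300_000 * i, "+",
            100.0, {"control": 0.25, "treated": 0.25},
        )
        for i in range(6)
    )
    return SimulationConfig(
        seed=3,
        layout=small_layout,
        bin_size=40_000,
        boundaries=boundaries,
        conditions=(("control", 0.0), ("treated", 0.5)),
        n_replicates=2,
        cis_depth=3e5,
        trans_bin_size=1_000_000,
        trans_rate=500.0,
        genes=genes,
        proseq_depth=1e5,
        n_tissues=4,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
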