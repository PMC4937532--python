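import numpy as np
import pytest

from sweepscan.io import GenotypeMatrix
from sweepscan.simulate import SimParams, simulate_dataset


@pytest.fixture
def small_gm() -> GenotypeMatrix:
    """8 sites x 6 samples (two panels of 3), handmade, fully deterministic."""
    calls = np.array(
        [
            [0, 0, 1, 1, 1, 1],
            [0, 1, 0, 1, 0, 1],
            [0, 0, 0, 1, 1, 1],
            [1, 1, 1, 0, 0, 0],
            [0, 0, 0, 0, 0, 1],
            [0, -1, 1, 1, -1, 0],
            [1, 1, 1, 1, 1, 0],
            [0, 1, 1, 0, 1, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        chrom=np.array(["chr1"] * 8, dtype=object),
        pos=np.array([100, 250, 400, 900, 1500, 2100, 2600, 3000]),
        ref=np.array(list("ACGTACGT"), dtype=object),
        alt=np.array(list("TGCAGTCA"), dtype=object),
        calls=calls,
        samples=[f"s{i}" for i in range(6)],
        panel=np.array(["A", "A", "A", "B", "B", "B"], dtype=object),
    ).validate()


@pytest.fixture(scope="session")
def swept_data() -> dict:
    """Default-parameter synthetic genome with planted sweeps (seed 1)."""
    return simulate_dataset(SimParams(rng_seed=1))


@pytest.fixture(scope="session")
def neutral_data() -> dict:
    """Default-size synthetic genome without sweeps (seed 2)."""
    return simulate_dataset(SimParams(rng_seed=2), with_sweeps=False)


@pytest.fixture(scope="session")
def swept_scan(swept_data) -> dict:
    from sweepscan.pipeline import run_full_scan

    p = swept_data["params"]
    return run_full_scan(
        swept_data["genotypes"], swept_data["annotation"],
        ancestral=swept_data["ancestral"], go_map=swept_data["go_map"],
        genome_bp=p.genome_bp,
    )


@pytest.fixture(scope="session")
def neutral_scan(neutral_data) -> dict:
    from sweepscan.pipeline import run_full_scan

    p = neutral_data["params"]
    return run_full_scan(
        neutral_data["genotypes"], neutral_data["annotation"],
        ancestral=neutral_data["ancestral"], genome_bp=p.genome_bp,
    )
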