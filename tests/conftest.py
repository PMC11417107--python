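import numpy as np
import pandas as pd
import pytest

from clonality.genotyper import CND, MUT, WT, StatusMatrix
from clonality.simdata import NoiseRates, simulate_case


def make_status(codes, tissues=None, regions=None, genes=None) -> StatusMatrix:
    """Hand-built status matrix from a list of status-code rows."""
    codes = np.asarray(codes, dtype=np.int8)
    n_cells, n_sites = codes.shape
    cells = pd.DataFrame(
        {
            "tissue": tissues or ["T"] * n_cells,
            "region": regions or (tissues or ["T"] * n_cells),
        },
        index=pd.Index([f"cell{i}" for i in range(n_cells)], name="cell"),
    )
    sites = pd.DataFrame(
        {"gene": genes or [f"G{j}" for j in range(n_sites)]},
        index=pd.Index([f"s{j}" for j in range(n_sites)], name="site"),
    )
    return StatusMatrix(
        pd.DataFrame(codes, index=cells.index, columns=sites.index), cells, sites
    )


@pytest.fixture(scope="session")
def poly_case():
    return simulate_case(seeding_mode="polyclonal", seed=3)


@pytest.fixture(scope="session")
def mono_case():
    return simulate_case(seeding_mode="monoclonal", seed=3)


@pytest.fixture(scope="session")
def default_noise():
    return NoiseRates()
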