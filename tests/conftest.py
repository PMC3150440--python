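import numpy as np
import pandas as pd
import pytest

from alumpanel import simulate as sim
from alumpanel.panel import GenotypeMatrix


@pytest.fixture(scope="session")
def small_panel():
    """K=3 structured panel, 90 lines x 200 markers on one chromosome."""
    cfg = sim.PanelConfig(
        K=3,
        lines_per_subpop=(30, 30, 30),
        markers_per_chrom=(200,),
        chrom_lengths=(2_000_000,),
        fst=0.35,
        missing_rate=0.01,
        seed=11,
    )
    return sim.simulate_panel(cfg)


@pytest.fixture(scope="session")
def small_controls(small_panel):
    """Five control lines per subpopulation of the small panel."""
    names = ["indica", "aus", "tropical_japonica"]
    return {f"{s}_{j}": s for s in names for j in range(5)}


@pytest.fixture
def toy_matrix():
    """Hand-built 4-line x 5-marker matrix with known calls."""
    calls = np.array(
        [
            [0, 2, 1, 0, 2],
            [0, 2, 1, 0, 2],
            [2, 0, 1, 2, 0],
            [2, 0, -1, 2, 0],
        ],
        dtype=np.int8,
    )
    markers = pd.DataFrame(
        {
            "id": [f"m{i}" for i in range(5)],
            "chrom": ["chr1"] * 5,
            "pos": [0, 100, 200, 300, 400],
        }
    )
    lines = pd.DataFrame({"id": ["a", "b", "c", "d"],
                          "subpop": ["indica", "indica", "aus", "aus"]})
    return GenotypeMatrix(calls, markers, lines)
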