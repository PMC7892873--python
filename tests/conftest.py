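import numpy as np
import pytest

from famrare.io import CohortDesign, GenotypeMatrix
from famrare.simulate import FamilySimConfig, simulate_family


@pytest.fixture
def family_result():
    """Default multiplex-family simulation (seed 0)."""
    return simulate_family(FamilySimConfig(seed=0))


@pytest.fixture
def small_cohort():
    """Deterministic 8-sample cohort (4 cases / 4 controls, 2 variants)."""
    ids = [f"s{i}" for i in range(8)]
    dosages = np.array(
        [
            [1, 0],
            [0, 1],
            [2, 0],
            [0, 0],
            [1, 1],
            [0, 0],
            [0, 1],
            [0, 0],
        ],
        dtype=np.int8,
    )
    gm = GenotypeMatrix(ids, ["1:100:A:G", "1:200:C:T"], dosages)
    design = CohortDesign(ids[:4], ids[4:])
    return gm, design


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return str(path)
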