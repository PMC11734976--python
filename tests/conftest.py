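import numpy as np
import pandas as pd
import pytest

from mnp_funnel.datasets import load_reference_ranks, load_reference_scores
from mnp_funnel.traj_analysis.core import Trajectory


@pytest.fixture(scope="session")
def reference_scores():
    return load_reference_scores()


@pytest.fixture(scope="session")
def reference_ranks():
    return load_reference_ranks()


def make_trajectory(coords: np.ndarray, elements=None, resids=None) -> Trajectory:
    """Assemble a bare trajectory around given (F, N, 3) coordinates."""
    from mnp_funnel.traj_analysis.core import element_mass, element_radius

    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    if elements is None:
        elements = ["C"] * n
    if resids is None:
        resids = list(range(1, n + 1))
    atoms = pd.DataFrame(
        {
            "name": [f"{e}{i}" for i, e in enumerate(elements)],
            "element": list(elements),
            "resname": ["UNK"] * n,
            "resid": resids,
            "chain": ["A"] * n,
            "radius": [element_radius(e) for e in elements],
            "mass": [element_mass(e) for e in elements],
        }
    )
    return Trajectory(atoms=atoms, coords=coords)
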