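import numpy as np
import pandas as pd
import pytest

from radmap import CrossSpec, GenotypeMatrix, simulate_family, simulate_true_map


def make_matrix(markers: dict[str, tuple[str, str, list[str]]]) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {marker: (p1, p2, offspring_calls)}."""
    n = len(next(iter(markers.values()))[2])
    calls = pd.DataFrame(
        {m: v[2] for m, v in markers.items()}, index=[f"off{k+1:03d}" for k in range(n)]
    ).T
    return GenotypeMatrix(
        calls=calls,
        p1=pd.Series({m: v[0] for m, v in markers.items()}),
        p2=pd.Series({m: v[1] for m, v in markers.items()}),
    )


@pytest.fixture(scope="session")
def small_family():
    """A 2-chromosome, 30-marker family at study-like noise levels."""
    tmap = simulate_true_map(2, 15, 100, seed=101)
    gm, truth = simulate_family(
        tmap, CrossSpec(n_offspring=94, missing_rate=0.05, error_rate=0.005, seed=102)
    )
    return tmap, gm, truth


@pytest.fixture(scope="session")
def clean_family():
    """A noise-free single-chromosome family for exact-recovery checks."""
    tmap = simulate_true_map(1, 20, 90, seed=7)
    gm, truth = simulate_family(
        tmap, CrossSpec(n_offspring=500, missing_rate=0.0, error_rate=0.0, seed=8)
    )
    return tmap, gm, truth
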