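import numpy as np
import pandas as pd
import pytest

from pondscape.io import OccurrenceMatrix, PondTable


def make_occ(inc, epoch="1957", site_prefix="P", species_prefix="S"):
    inc = np.asarray(inc)
    return OccurrenceMatrix(
        epoch,
        [f"{site_prefix}{i+1}" for i in range(inc.shape[0])],
        [f"{species_prefix}{j+1}" for j in range(inc.shape[1])],
        inc,
    )


@pytest.fixture
def toy_3site():
    """Sites A={s1}, B={s1,s2}, C={s3}: the worked enumeration example."""
    return make_occ([[1, 0, 0], [1, 1, 0], [0, 0, 1]])


@pytest.fixture
def pond_table_3():
    df = pd.DataFrame(
        {
            "pond_id": ["A", "B", "C"],
            "x": [0.0, 1000.0, 2000.0],
            "y": [0.0, 0.0, 0.0],
            "area_1957": [1.0, 2.0, 4.0],
            "area_2010": [0.5, np.nan, 2.0],
            "cond_1957": [1.0, 3.0, 2.0],
            "cond_2010": [2.0, np.nan, 3.0],
            "extant_1957": [True, True, True],
            "extant_2010": [True, False, True],
            "sampled_1957": [True, True, True],
            "sampled_2010": [True, False, True],
        }
    ).set_index("pond_id")
    return PondTable(df)


@pytest.fixture
def random_occ():
    """Factory for random incidence matrices without empty species columns."""

    def _make(n_sites, n_species, seed, p=0.4, epoch="1957"):
        rng = np.random.default_rng(seed)
        while True:
            inc = (rng.random((n_sites, n_species)) < p).astype(np.int8)
            if (inc.sum(axis=0) > 0).all() and (inc.sum(axis=1) > 0).all():
                return make_occ(inc, epoch=epoch)

    return _make
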