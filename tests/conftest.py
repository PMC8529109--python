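import numpy as np
import pandas as pd
import pytest

from funcstab.io_profiles import COLUMNS, LinkedProfile
from funcstab.synthetic_data import SyntheticConfig, generate_community


def make_profile(rows):
    """Build a LinkedProfile from (sample, genus, phylum, function, l1, l2, l3, hits) tuples."""
    return LinkedProfile(pd.DataFrame(rows, columns=list(COLUMNS)))


@pytest.fixture
def toy_profile():
    """Six records, three samples, three phyla, two level-1 categories."""
    return make_profile([
        ("s1", "g1", "P1", "f1", "c1", "m1", "b1", 5),
        ("s1", "g2", "P2", "f2", "c1", "m1", "b2", 3),
        ("s2", "g1", "P1", "f2", "c1", "m1", "b2", 2),
        ("s2", "g3", "P3", "f3", "c2", "m2", "b3", 4),
        ("s3", "g2", "P2", "f1", "c1", "m1", "b1", 6),
        ("s3", "g3", "P3", "f3", "c2", "m2", "b3", 1),
    ])


@pytest.fixture(scope="session")
def small_config():
    """Small but non-degenerate synthetic community used by several suites."""
    return SyntheticConfig(
        n_samples=10, n_phyla=5, genera_per_phylum=4, n_functions=40,
        redundancy=0.9, phylum_decay=0.6, depth=5_000, dispersion=0.4, seed=7,
    )


@pytest.fixture(scope="session")
def small_community(small_config):
    return generate_community(small_config)


def abundance_frame(arr, kind="taxonomy", level="genus", relative=False):
    """Wrap a 2-D array in an AbundanceTable with generated ids."""
    from funcstab.io_profiles import AbundanceTable

    arr = np.asarray(arr, dtype=float)
    return AbundanceTable(
        values=pd.DataFrame(
            arr,
            index=[f"s{i}" for i in range(arr.shape[0])],
            columns=[f"f{j}" for j in range(arr.shape[1])],
        ),
        kind=kind,
        level=level,
        relative=relative,
    )
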