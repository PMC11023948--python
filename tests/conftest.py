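import numpy as np
import pytest

from espdyn import default_matrix
from espdyn.geodata import ChangeRecord, Mosaic, Patch
from espdyn.synthetic import table1_scenario


@pytest.fixture(scope="session")
def matrix():
    return default_matrix()


@pytest.fixture(scope="session")
def toy():
    """The three-patch worked example: (mosaic 2012, mosaic 2018, boundaries)."""
    return table1_scenario()


def random_instance(seed: int, n_patches: int = 20, n_changes: int = 8):
    """A small random mosaic plus change records (no geometry) for oracle checks."""
    rng = np.random.default_rng(seed)
    codes = list(default_matrix().classes)
    patches = tuple(
        Patch(
            patch_id=f"p{i}",
            lulc=codes[rng.integers(len(codes))],
            area=float(rng.uniform(0.5, 40.0)),
        )
        for i in range(n_patches)
    )
    records = []
    for i in range(n_changes):
        old, new = rng.choice(len(codes), size=2, replace=False)
        records.append(
            ChangeRecord(
                patch_id=f"c{i}",
                old_lulc=codes[old],
                new_lulc=codes[new],
                area=float(rng.uniform(0.1, 10.0)),
            )
        )
    return Mosaic(patches, epoch="t"), records
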