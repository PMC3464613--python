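import numpy as np
import pandas as pd
import pytest

from dartpop import marker_io, synthetic_data

NA = float("nan")


@pytest.fixture
def toy_genotypes() -> marker_io.GenotypeMatrix:
    """3 lines x 4 markers with one missing call (missing rate 1/12)."""
    calls = np.array(
        [
            [0, 1, 0, 1],
            [1, 1, NA, 0],
            [0, 0, 1, 1],
        ],
        dtype=float,
    )
    return marker_io.GenotypeMatrix(
        ["L1", "L2", "L3"], ["m1", "m2", "m3", "m4"], calls,
        ["winter", "spring", "spring"],
    )


@pytest.fixture
def toy_map() -> marker_io.GeneticMap:
    return marker_io.GeneticMap(pd.DataFrame(
        {"linkage_group": ["1A", "1A", "2R-1", "1A"],
         "position_cM": [0.0, 4.2, 0.0, 9.9]},
        index=["m1", "m2", "m3", "m4"],
    ))


@pytest.fixture
def toy_dataset(toy_genotypes, toy_map) -> marker_io.AlignedDataset:
    return marker_io.align(toy_genotypes, toy_map)


def make_dataset(calls, habit=None, positions=None, groups=None) -> marker_io.AlignedDataset:
    """AlignedDataset from a raw call matrix; one linkage group, unit spacing
    unless positions/groups are given."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    if positions is None:
        positions = np.arange(m, dtype=float)
    if groups is None:
        groups = ["1A"] * m
    gm = marker_io.GenotypeMatrix(
        [f"L{i}" for i in range(n)], [f"m{j}" for j in range(m)], calls,
        habit or ["unknown"] * n,
    )
    gmap = marker_io.GeneticMap(pd.DataFrame(
        {"linkage_group": groups, "position_cM": positions}, index=gm.marker_ids))
    return marker_io.align(gm, gmap)


@pytest.fixture(scope="session")
def small_sim():
    """Seeded two-subpopulation panel with one planted divergence region."""
    cfg = synthetic_data.SimConfig(
        seed=7,
        n_lines=(40, 40),
        founders=(12, 4),
        generations=3.0,
        missing_rate=0.03,
        linkage_groups=[
            synthetic_data.LinkageGroupSpec("1A", 100.0, 60),
            synthetic_data.LinkageGroupSpec("1B", 100.0, 60),
            synthetic_data.LinkageGroupSpec("1R", 100.0, 60),
        ],
        planted_regions=[synthetic_data.PlantedRegion("1R", 30.0, 60.0, 0.8)],
    )
    gm, gmap, truth = synthetic_data.simulate(cfg)
    return gm, gmap, truth, cfg


@pytest.fixture(scope="session")
def small_dataset(small_sim) -> marker_io.AlignedDataset:
    gm, gmap, _, _ = small_sim
    return marker_io.align(gm, gmap)
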