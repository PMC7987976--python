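import numpy as np
import pandas as pd
import pytest

from guidescreen.counts import CountMatrix
from guidescreen.library import build_synthetic_library
from guidescreen.simulate import ScreenDesign, SelectionProfile, simulate_screen


@pytest.fixture(scope="session")
def small_library():
    return build_synthetic_library(10, 5, 5, protospacer_length=20, seed=11)


@pytest.fixture(scope="session")
def small_design():
    return ScreenDesign(
        n_mice_per_group=6,
        dose_cells=4_000,
        control_cells=20_000,
        n_transduced_cells=200_000,
        read_depth=60_000,
    )


@pytest.fixture(scope="session")
def small_screen(small_library, small_design):
    sel = SelectionProfile(
        gene_effect={"gene01": 0.6, "gene02": 0.6},
        survival_prob=0.05,
        dispersion=0.0,
    )
    return simulate_screen(small_design, sel, small_library, seed=202)


def make_count_matrix(values: dict, genes: dict, groups: dict, normalized=False) -> CountMatrix:
    df = pd.DataFrame(values)
    return CountMatrix(df, pd.Series(genes), groups, normalized=normalized)


@pytest.fixture
def tiny_matrix():
    """4 guides x 4 samples (2 controls, 1 per lung group)."""
    values = {
        "cells_500x_1": [100, 40, 0, 35],
        "cells_500x_2": [90, 55, 0, 30],
        "lung_4h_m01": [80, 10, 0, 100],
        "lung_19d_m01": [500, 0, 0, 20],
    }
    genes = {"g1": "geneA", "g2": "geneA", "g3": "geneB", "g4": "NTC"}
    groups = {
        "cells_500x_1": "cells_500x",
        "cells_500x_2": "cells_500x",
        "lung_4h_m01": "lung_4h",
        "lung_19d_m01": "lung_19d",
    }
    df = pd.DataFrame(values, index=["g1", "g2", "g3", "g4"])
    return CountMatrix(df, pd.Series(genes), groups)
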