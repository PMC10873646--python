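"""Shared fixtures: every dataset is generated programmatically at test time."""

import warnings

import numpy as np
import pytest

from sparkquant import synthetic

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def imaging_gt() -> synthetic.ImagingGroundTruth:
    """Default imaging conditions: c_sat 40 nM, partition ratio 7.5."""
    return synthetic.ImagingGroundTruth(seed=42)


@pytest.fixture(scope="session")
def phase_cells(imaging_gt):
    """100 cells log-spaced over 5-500 nM, with truth table (session-cached)."""
    conc = np.geomspace(5, 500, 100)
    cells, truth = synthetic.generate_cell_images(imaging_gt, conc)
    return cells, truth


@pytest.fixture(scope="session")
def fusion_movies():
    gt = synthetic.FusionGroundTruth(seed=42)
    movies, truth = synthetic.generate_fusion_movie(gt)
    return gt, movies, truth
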