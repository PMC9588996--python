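"""Shared fixtures: a control lobule, its count matrix, and a decode fixture.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive simulations to one run each.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=UserWarning, module="umap")
warnings.filterwarnings("ignore", category=FutureWarning)

from lobulemap.cellquant import assign_spots_to_cells, filter_non_hepatocytes, qc_filter_cells
from lobulemap.clustering import normalize_counts
from lobulemap.codebook import build_codebook
from lobulemap.synthetic import (
    default_panel,
    render_image_rounds,
    simulate_lobule,
    simulate_spot_field,
    simulate_spots,
)

LOBULE_SEED = 1
SPOT_SEED = 2


@pytest.fixture(scope="session")
def panel():
    return default_panel(100)


@pytest.fixture(scope="session")
def lobule(panel):
    """Control-condition lobule: geometry, cells, spots, ground truth."""
    geometry, cells = simulate_lobule(LOBULE_SEED, n_cells=800)
    spots, truth = simulate_spots(cells, panel, seed=SPOT_SEED, geometry=geometry)
    return {"geometry": geometry, "cells": cells, "spots": spots, "truth": truth}


@pytest.fixture(scope="session")
def hepatocyte_counts(panel, lobule):
    """QC-passed hepatocyte count matrix of the control lobule."""
    counts, _ = assign_spots_to_cells(lobule["spots"], lobule["cells"], genes=panel.names)
    return filter_non_hepatocytes(qc_filter_cells(counts))


@pytest.fixture(scope="session")
def normalized(hepatocyte_counts):
    return normalize_counts(hepatocyte_counts)


@pytest.fixture(scope="session")
def codebook24():
    return build_codebook(24, n_unused=8, seed=3)


@pytest.fixture(scope="session")
def rendered_field(codebook24):
    """300 well-separated spots rendered into 16 drifting stacks."""
    spots = simulate_spot_field(300, codebook24.genes, seed=5)
    stacks, transforms, log = render_image_rounds(spots, codebook24, seed=7)
    return {"spots": spots, "stacks": stacks, "transforms": transforms, "log": log}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
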