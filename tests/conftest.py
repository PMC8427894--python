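import numpy as np
import pandas as pd
import pytest

from memscape.connectivity import gabriel_graph, to_weight_matrix
from memscape.datamodel import SiteTable
from memscape.simulate import SimulationParams, generate_dataset


def make_sites(coords, habitats=None, ids=None) -> SiteTable:
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if habitats is None:
        habitats = ["Crop", "Edge", "Oak", "Wasteland"] * (n // 4 + 1)
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    return SiteTable(site_ids=tuple(ids), coords=coords, habitat=tuple(habitats[:n]))


def random_sites(rng: np.random.Generator, n: int = 23, extent: float = 10.0) -> SiteTable:
    return make_sites(rng.uniform(0, extent, size=(n, 2)))


@pytest.fixture
def square_sites() -> SiteTable:
    """Four sites at the unit-square corners (co-circular, exercises tie rules)."""
    return make_sites([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def path4_sites() -> SiteTable:
    """Four collinear-avoiding sites whose Gabriel graph is the path 0-1-2-3."""
    return make_sites([(0, 0), (1, 0.05), (2, 0), (3, 0.05)])


@pytest.fixture(scope="session")
def broad_dataset():
    """Landscape with a broad-scale environmental gradient only (study-like size)."""
    return generate_dataset(SimulationParams(seed=11, broad_effect=1.0, fine_effect=0.0))


@pytest.fixture(scope="session")
def gabriel_weights(broad_dataset):
    return to_weight_matrix(gabriel_graph(broad_dataset.sites), "binary")


# --- study-condition fixture parameters, shared by tests and the acceptance suite ---

#: habitat -> abundance-concentration used when habitat must drive diversity
EVENNESS_GRADIENT = {"Crop": 2.5, "Edge": 1.5, "Oak": 0.75, "Wasteland": 0.0}


def discrimination_params(seed: int) -> SimulationParams:
    """Habitat drives diversity (evenness gradient), not the spatial eigenstructure."""
    return SimulationParams(
        seed=seed,
        broad_effect=0.6,
        fine_effect=0.0,
        habitat_evenness=EVENNESS_GRADIENT,
        habitat_offset_sd=0.15,
    )


def fine_only_params(seed: int) -> SimulationParams:
    """Fine-scale signal injected through a trailing MEM; no broad gradient."""
    return SimulationParams(seed=seed, broad_effect=0.0, fine_effect=1.5, habitat_offset_sd=0.0)


def null_params(seed: int) -> SimulationParams:
    """No injected spatial or habitat structure (type-I calibration conditions)."""
    return SimulationParams(seed=seed, broad_effect=0.0, fine_effect=0.0, habitat_offset_sd=0.0)
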