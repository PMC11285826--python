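import numpy as np
import pytest

from biofilmsim.geometry import CellState
from biofilmsim.params import ModelParams


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240618)


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def make_cell(rng: np.random.Generator, cid: int = 0, Lstar: float = 2.6,
              box: float = 5.0, zmin: float = 0.0) -> CellState:
    r = rng.uniform(-box, box, 3)
    r[2] = rng.uniform(zmin, zmin + box)
    return CellState(cid, r, random_unit_vector(rng), Lstar)


@pytest.fixture
def cell_factory():
    return make_cell


def brute_segment_distance(r1, e1, h1, r2, e2, h2, n=1000) -> float:
    """Brute-force minimum distance by dense sampling of both segments."""
    s = np.linspace(-h1, h1, n)
    t = np.linspace(-h2, h2, n)
    p1 = r1[None, :] + s[:, None] * e1[None, :]
    p2 = r2[None, :] + t[:, None] * e2[None, :]
    d2 = ((p1 ** 2).sum(1)[:, None] + (p2 ** 2).sum(1)[None, :]
          - 2.0 * p1 @ p2.T)
    return float(np.sqrt(max(d2.min(), 0.0)))
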