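import dendropy
import numpy as np
import pytest

from refugia.grids import GridSpec
from refugia.sdm import RangeAtlas, SpeciesRange
from refugia.synthetic import generate_environment


@pytest.fixture
def grid10() -> GridSpec:
    return GridSpec(10, 10)


@pytest.fixture
def env10(grid10) -> "EnvStack":
    return generate_environment(grid10, n_layers=3, correlation_length=2.0, seed=7)


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def make_atlas(grid: GridSpec, presences: dict[str, np.ndarray], scenario: str = "current") -> RangeAtlas:
    """Atlas over one scenario from explicit boolean grids."""
    ranges = {
        (sid, scenario): SpeciesRange(sid, scenario, np.asarray(p, dtype=bool))
        for sid, p in presences.items()
    }
    return RangeAtlas(grid, ranges, list(presences), [scenario])


def morans_i(values: np.ndarray) -> float:
    """Lag-1 (rook neighbors) Moran's I of a 2-D field."""
    z = values - values.mean()
    num = (z[:-1, :] * z[1:, :]).sum() + (z[:, :-1] * z[:, 1:]).sum()
    w_total = z[:-1, :].size + z[:, :-1].size
    return float((values.size / w_total) * num / (z**2).sum())
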