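import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from airhealth.gridio import Grid, SurfaceStack
from airhealth.synthetic import RegionConfig, generate_region


@pytest.fixture(scope="session")
def small_config() -> RegionConfig:
    """A fast-to-generate region used by most integration tests."""
    return RegionConfig(n_rows=6, n_cols=12, n_stations=20, seed=7)


@pytest.fixture(scope="session")
def small_region(small_config):
    return generate_region(small_config)


@pytest.fixture(scope="session")
def default_region():
    return generate_region(RegionConfig(seed=11))


def lattice_units(n_rows: int, n_cols: int, size: float = 1.0) -> pd.DataFrame:
    """A bare square-lattice unit table (no attributes)."""
    records = []
    for r in range(n_rows):
        for c in range(n_cols):
            records.append(
                {
                    "unit_id": f"u{r}_{c}",
                    "city": "C1",
                    "geometry": Polygon(
                        [
                            (c * size, r * size),
                            ((c + 1) * size, r * size),
                            ((c + 1) * size, (r + 1) * size),
                            (c * size, (r + 1) * size),
                        ]
                    ),
                }
            )
    return pd.DataFrame.from_records(records)


def constant_stack(value: float, shape=(20, 20), cell_size=1000.0, landcover=None) -> SurfaceStack:
    """A single-covariate stack with a spatially constant field."""
    surfaces = {"elevation": Grid(np.full(shape, value), cell_size=cell_size)}
    if landcover is not None:
        surfaces["landcover"] = Grid(landcover, cell_size=cell_size)
    return SurfaceStack(surfaces)
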