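import numpy as np
import pytest

from fcdecode.synthetic import (
    CohortConfig,
    PlantedExpressionConfig,
    generate_bold_cohort,
    generate_expression_matrix,
)
from fcdecode.types import BoldSeries


def make_series(
    data: np.ndarray,
    tr: float = 1.2,
    voxel_size=(1.0, 1.0, 1.0),
    mask: np.ndarray | None = None,
) -> BoldSeries:
    """Wrap a raw 4D array in a BoldSeries with an all-true mask by default."""
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldSeries(data=data, voxel_size_mm=voxel_size, tr_seconds=tr, brain_mask=mask)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny two-group cohort with a strong planted effect in group b."""
    cfg = CohortConfig(
        n_group_a=4,
        n_group_b=4,
        grid_shape=(8, 8, 2),
        n_timepoints=120,
        n_regions=6,
        planted_pair=(2, 5),
        planted_corr_a=0.0,
        planted_corr_b=0.6,
        rng_seed=42,
    )
    return generate_bold_cohort(cfg)


@pytest.fixture(scope="session")
def planted_expression():
    """Default planted expression matrix (raw) with its annotations."""
    cfg = PlantedExpressionConfig(rng_seed=5)
    matrix, annotations = generate_expression_matrix(cfg)
    return cfg, matrix, annotations
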