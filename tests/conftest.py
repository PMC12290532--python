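import numpy as np
import pytest

from prepdecode.bold import PlantedEffectSpec, default_roi_masks
from prepdecode.design import DesignSpec, generate_design

SMALL_GRID = (12, 10, 8)


def small_effects(**overrides) -> PlantedEffectSpec:
    """Planted-effect spec on a desk-scale grid with 3-voxel ROI cubes."""
    kwargs = dict(grid_shape=SMALL_GRID,
                  roi_masks=default_roi_masks(SMALL_GRID, roi_extent=3))
    kwargs.update(overrides)
    return PlantedEffectSpec(**kwargs)


def null_effects(**overrides) -> PlantedEffectSpec:
    """All planted amplitudes zero: pure-noise data."""
    zero = {c: {r: 0.0 for r in ("itg-like", "occ-like", "fg-like", "fo-like")}
            for c in ("attention", "expectation")}
    kwargs = dict(category_amplitude=zero, shared_pattern_weight=0.0,
                  reinstatement_weight=0.0, condition_amplitude=0.0,
                  shape_amplitude=0.0, target_amplitude=0.0)
    kwargs.update(overrides)
    return small_effects(**kwargs)


@pytest.fixture(scope="session")
def small_spec() -> DesignSpec:
    """Reduced session: 8 runs of 24 trials (24 is divisible by 8 and 6)."""
    return DesignSpec(trials_per_run=24, seed=11)


@pytest.fixture(scope="session")
def small_trials(small_spec):
    return generate_design(small_spec)


@pytest.fixture(scope="session")
def roi_masks() -> dict[str, np.ndarray]:
    return default_roi_masks(SMALL_GRID, roi_extent=3)
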