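import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from hierseg import (
    FlatSegmentation,
    FrameLabelGrid,
    Hierarchy,
    Segment,
)


@pytest.fixture
def two_level_hierarchy() -> Hierarchy:
    """A small AABA-style hierarchy: 3 coarse sections, 6 fine phrases."""
    coarse = FlatSegmentation(
        (
            Segment(0.0, 12.0, "A"),
            Segment(12.0, 24.0, "B"),
            Segment(24.0, 36.0, "A"),
        )
    )
    fine = FlatSegmentation(
        (
            Segment(0.0, 6.0, "a"),
            Segment(6.0, 12.0, "b"),
            Segment(12.0, 18.0, "c"),
            Segment(18.0, 24.0, "c"),
            Segment(24.0, 30.0, "a"),
            Segment(30.0, 36.0, "b"),
        )
    )
    return Hierarchy((coarse, fine))


@pytest.fixture
def micro_grids() -> tuple[FrameLabelGrid, FrameLabelGrid]:
    """The 4-frame worked example: (AABB; abcc) vs (AAAB; aabb)."""
    g_ref = FrameLabelGrid(10.0, np.array([[0, 0, 1, 1], [0, 1, 2, 2]]))
    g_est = FrameLabelGrid(10.0, np.array([[0, 0, 0, 1], [0, 0, 1, 1]]))
    return g_ref, g_est


def random_grid(rng: np.random.Generator, n_frames: int, depth: int, n_labels: int = 4) -> FrameLabelGrid:
    """Random frame label grid; levels are independent (non-nested)."""
    labels = rng.integers(0, n_labels, size=(depth, n_frames))
    return FrameLabelGrid(10.0, labels)
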