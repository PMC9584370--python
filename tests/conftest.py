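"""Shared fixtures: phantoms and measurements reused across test modules."""

import numpy as np
import pytest

from blebquant import (
    LabelVolume,
    MeasureConfig,
    PhantomSpec,
    make_phantom,
    measure,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Default (non-merged) phantom with its ground truth."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def merged_phantom():
    return make_phantom(PhantomSpec(merged=True))


@pytest.fixture(scope="session")
def measured_default(default_phantom):
    """Default phantom measured at a coarse-but-fast 0.2 mm analysis grid."""
    vol, gt = default_phantom
    m = measure(
        vol,
        MeasureConfig(resolution=0.2),
        fenestration_axes=gt.fenestration_axes,
        fenestration_radius=gt.fenestration_radius,
        globe_center=gt.globe_center,
    )
    return m, gt


def ball_mask_volume(radius: float, spacing: float, label: int = 1,
                     margin: float = 2.0, center=(0.0, 0.0, 0.0)) -> LabelVolume:
    """Analytic ball label map used by several geometry tests."""
    n = int(np.ceil(2 * (radius + margin) / spacing)) | 1
    c = (np.arange(n) - (n - 1) / 2) * spacing
    x, y, z = np.meshgrid(c - center[0], c - center[1], c - center[2], indexing="ij")
    mask = (x * x + y * y + z * z <= radius * radius).astype(np.int16) * label
    return LabelVolume(mask, (spacing,) * 3,
                       origin=(c[0], c[0], c[0]), label_map={"globe": label})
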