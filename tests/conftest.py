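import numpy as np
import pytest
from scipy import ndimage

from tibdefect.phantom import demo_spec, generate_phantom
from tibdefect.segmentation import segment_hu, split_tibia_fibula


@pytest.fixture(scope="session")
def demo_phantom():
    """Noise-free canonical phantom (one medial metaphyseal defect, IIa)."""
    return generate_phantom(demo_spec())


@pytest.fixture(scope="session")
def demo_segmented(demo_phantom):
    """The demo phantom re-segmented from its HU volume."""
    ct, _ = demo_phantom
    return split_tibia_fibula(segment_hu(ct))


def boundary_shell(true_labels: np.ndarray) -> np.ndarray:
    """One-voxel shell around every class boundary of a label array."""
    shell = np.zeros(true_labels.shape, dtype=bool)
    for c in np.unique(true_labels):
        m = true_labels == c
        shell |= m & ~ndimage.binary_erosion(m)
    return ndimage.binary_dilation(shell, np.ones((3, 3, 3), dtype=bool))
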