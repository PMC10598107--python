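"""HU-threshold segmentation: overlap/gap rules, phantom recovery, robustness."""

import numpy as np
import pytest

from tibdefect.image import CTVolume, Label, LabelMap
from tibdefect.phantom import demo_spec, generate_phantom
from tibdefect.segmentation import ThresholdSet, segment_hu, split_tibia_fibula

from conftest import boundary_shell


def make_ct(hu_array, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.asarray(hu_array, dtype=np.int16), spacing)


def test_uniform_implant_volume():
    ct = make_ct(np.full((8, 8, 8), 2500))
    lab = segment_hu(ct)
    assert (lab.labels == Label.IMPLANT).all()


@pytest.mark.filterwarnings("ignore:no implant")
def test_all_air_volume_raises():
    ct = make_ct(np.full((8, 8, 8), -1000))
    with pytest.raises(ValueError, match="no foreground"):
        segment_hu(ct)


def test_no_implant_warns_and_cement_empty():
    hu = np.full((10, 10, 10), -1000)
    hu[2:8, 2:8, 2:8] = 850  # cement-range HU, but nothing to be adjacent to
    with pytest.warns(UserWarning, match="no implant"):
        lab = segment_hu(make_ct(hu))
    assert not (lab.labels == Label.CEMENT).any()
    assert (lab.labels[2:8, 2:8, 2:8] == Label.BONE_TIBIA).all()


def test_cement_adjacency_rule():
    """HU 850 far from the implant is bone; the same HU adjacent to it is cement."""
    hu = np.full((60, 9, 9), -1000)
    hu[0:4, 3:6, 3:6] = 2500       # implant block
    hu[4:8, 3:6, 3:6] = 850        # adjacent: cement
    hu[50:54, 3:6, 3:6] = 850      # 30+ mm away: bone
    lab = segment_hu(make_ct(hu), cement_adjacency_mm=3.0)
    assert (lab.labels[4:7, 3:6, 3:6] == Label.CEMENT).any()
    assert (lab.labels[50:54, 3:6, 3:6] == Label.BONE_TIBIA).all()


def test_cement_class_monotone_in_adjacency():
    ct, _ = _small_interface_volume()
    sizes = []
    for adj in (0.0, 1.0, 2.0, 4.0, 8.0):
        lab = segment_hu(ct, cement_adjacency_mm=adj)
        sizes.append(int((lab.labels == Label.CEMENT).sum()))
    assert sizes == sorted(sizes)


def _small_interface_volume():
    hu = np.full((20, 20, 20), -1000)
    hu[4:16, 4:16, 4:10] = 2500
    hu[4:16, 4:16, 10:18] = 850
    return make_ct(hu), hu


@pytest.mark.filterwarnings("ignore:no implant")
def test_exact_200_hu_is_bone_not_defect():
    hu = np.full((12, 12, 12), 1000)
    hu[5, 5, 5] = 200
    hu[6, 6, 6] = 199
    lab = segment_hu(make_ct(hu))
    assert lab.labels[5, 5, 5] == Label.BONE_TIBIA
    assert lab.labels[6, 6, 6] == Label.DEFECT  # interior void


def test_gap_hu_rim_goes_to_implant_near_metal_else_bone():
    hu = np.full((20, 9, 9), 1000)
    hu[0:5, :, :] = 2500
    hu[5, 4, 4] = 1900   # touching the implant: partial-volume rim
    hu[15, 4, 4] = 1900  # far from it: bone
    lab = segment_hu(make_ct(hu))
    assert lab.labels[5, 4, 4] == Label.IMPLANT
    assert lab.labels[15, 4, 4] == Label.BONE_TIBIA


@pytest.mark.filterwarnings("ignore:no implant")
def test_enclosed_void_is_defect_exterior_air_is_background():
    hu = np.full((24, 24, 24), -1000)
    hu[4:20, 4:20, 4:20] = 1000
    hu[10:14, 10:14, 10:14] = -400  # enclosed osteolytic cavity
    lab = segment_hu(make_ct(hu))
    assert (lab.labels[10:14, 10:14, 10:14] == Label.DEFECT).all()
    assert lab.labels[0, 0, 0] == Label.BACKGROUND


def test_label_conservation(demo_segmented):
    counts = np.bincount(demo_segmented.labels.reshape(-1), minlength=6)
    assert counts.sum() == np.prod(demo_segmented.shape)


def test_noise_free_phantom_resegments_to_ground_truth(demo_phantom, demo_segmented):
    """Recovered labels equal truth outside a one-voxel boundary shell."""
    _, gt = demo_phantom
    true = gt.true_labels.labels
    mismatch = demo_segmented.labels != true
    assert not (mismatch & ~boundary_shell(true)).any()
    # and the mismatching fraction itself is tiny
    assert mismatch.mean() < 1e-4


def test_resegmentation_idempotent(demo_segmented):
    """Synthesizing HU from a label map's class midpoints and re-segmenting
    returns the same label map away from boundaries."""
    from tibdefect.phantom import HU_AIR, HU_BONE, HU_CEMENT, HU_DEFECT, HU_IMPLANT

    midpoints = {
        Label.BACKGROUND: HU_AIR, Label.BONE_TIBIA: HU_BONE,
        Label.BONE_FIBULA: HU_BONE, Label.CEMENT: HU_CEMENT,
        Label.IMPLANT: HU_IMPLANT, Label.DEFECT: HU_DEFECT,
    }
    hu = np.zeros(demo_segmented.shape, dtype=np.int16)
    for lab, val in midpoints.items():
        hu[demo_segmented.labels == lab] = val
    relab = split_tibia_fibula(
        segment_hu(CTVolume(hu, demo_segmented.spacing_mm))
    )
    mismatch = relab.labels != demo_segmented.labels
    assert not (mismatch & ~boundary_shell(demo_segmented.labels)).any()


def test_noise_robustness_dice():
    """Per-class Dice >= 0.95 against ground truth at 50 HU noise."""
    ct, gt = generate_phantom(demo_spec(noise_sd_hu=50.0, seed=2))
    seg = split_tibia_fibula(segment_hu(ct))
    for c in (Label.BONE_TIBIA, Label.BONE_FIBULA, Label.CEMENT, Label.IMPLANT, Label.DEFECT):
        a = seg.labels == c
        b = gt.true_labels.labels == c
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice >= 0.95, c


def test_split_recovers_fibula_count(demo_phantom, demo_segmented):
    _, gt = demo_phantom
    n_true = int(gt.true_labels.mask(Label.BONE_FIBULA).sum())
    n_seg = int(demo_segmented.mask(Label.BONE_FIBULA).sum())
    assert n_seg == pytest.approx(n_true, rel=0.01)


@pytest.mark.filterwarnings("ignore:no implant")
def test_split_without_fibula_leaves_class_empty():
    hu = np.full((20, 20, 20), -1000)
    hu[5:15, 5:15, 2:18] = 1000
    lab = split_tibia_fibula(segment_hu(make_ct(hu)))
    assert not (lab.labels == Label.BONE_FIBULA).any()
    assert (lab.labels == Label.BONE_TIBIA).any()


def test_split_tie_broken_by_proximal_mass():
    """Two equal blobs: the one with more voxels in the proximal half is tibia."""
    lab = np.zeros((30, 10, 20), dtype=np.uint8)
    lab[2:8, 2:8, 0:6] = Label.BONE_TIBIA     # proximal blob
    lab[20:26, 2:8, 12:18] = Label.BONE_TIBIA  # distal blob, same size, more lateral
    out = split_tibia_fibula(LabelMap(lab, (1, 1, 1)))
    assert (out.labels[2:8, 2:8, 0:6] == Label.BONE_TIBIA).all()
    assert (out.labels[20:26, 2:8, 12:18] == Label.BONE_FIBULA).all()


def test_threshold_set_validation():
    with pytest.raises(ValueError):
        ThresholdSet(implant_range=(1500, 3071))
    t = ThresholdSet.from_dict({"defect": [-1024, 200], "implant": [2000, 3071]})
    assert t.defect_range == (-1024, 200)
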