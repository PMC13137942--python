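"""Component cleanup, PCA geometry against analytic boxes, and
OBB-aligned ROI extraction."""

import numpy as np
import pytest

from cspine.ctio import CTVolume, SegLabelVolume
from cspine.postprocess import (clean_labels, extract_roi,
                                vertebra_geometry)


def _box_labels(shape, spacing, lo, hi, level=1):
    lab = np.zeros(shape, dtype=np.int16)
    lab[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = level
    return SegLabelVolume(lab, spacing)


def test_clean_labels_idempotent_and_removes_satellites(small_sample):
    cleaned = clean_labels(small_sample.labels)
    assert np.array_equal(cleaned.labels, small_sample.labels.labels)

    lab = small_sample.labels.labels.copy()
    lab[0:2, 0:2, 0:2] = 3  # 8-voxel satellite far from the real C3
    noisy = SegLabelVolume(lab, small_sample.labels.spacing)
    cleaned = clean_labels(noisy)
    assert cleaned.labels[0, 0, 0] == 0
    again = clean_labels(cleaned)
    assert np.array_equal(again.labels, cleaned.labels)
    for k in range(1, 8):
        assert (cleaned.labels == k).sum() <= (noisy.labels == k).sum()


def test_geometry_axis_aligned_box():
    """A 20x10x6 mm solid box: principal axes = coordinate axes (x, y, z
    by descending variance), extents within a voxel of the box size."""
    spacing = (1.0, 1.0, 1.0)
    vol = _box_labels((40, 40, 40), spacing, (5, 10, 15), (25, 20, 21))
    geom = vertebra_geometry(vol, None, 1)
    assert geom is not None
    assert np.allclose(geom.centroid, (14.5, 14.5, 17.5))
    ref = np.eye(3)
    for i in range(3):
        assert abs(abs(geom.axes[i] @ ref[i]) - 1.0) < 1e-6
    assert np.allclose(geom.extents, (20, 10, 6), atol=1.01)
    assert geom.voxel_count == 20 * 10 * 6


def test_geometry_rotated_box_recovers_direction():
    """A box rotated 30 degrees about z: first principal axis within 2
    degrees of the rotated long direction."""
    spacing = (0.5, 0.5, 0.5)
    n = 80
    idx = np.indices((n, n, n)).reshape(3, -1).T * spacing
    center = np.array([20.0, 20.0, 20.0])
    th = np.radians(30.0)
    rot = np.array([[np.cos(th), -np.sin(th), 0],
                    [np.sin(th), np.cos(th), 0],
                    [0, 0, 1]])
    local = (idx - center) @ rot  # coordinates in the box frame
    inside = (np.abs(local[:, 0]) <= 10) & (np.abs(local[:, 1]) <= 4) \
        & (np.abs(local[:, 2]) <= 2)
    lab = np.zeros(n ** 3, dtype=np.int16)
    lab[inside] = 2
    vol = SegLabelVolume(lab.reshape(n, n, n), spacing)
    geom = vertebra_geometry(vol, None, 2)
    long_dir = rot[:, 0]
    cos = abs(geom.axes[0] @ long_dir)
    assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 2.0


def test_geometry_single_voxel_and_missing_level():
    spacing = (1.0, 2.0, 3.0)
    lab = np.zeros((10, 10, 10), dtype=np.int16)
    lab[4, 5, 6] = 7
    vol = SegLabelVolume(lab, spacing)
    geom = vertebra_geometry(vol, None, 7)
    assert np.allclose(geom.centroid, (4.0, 10.0, 18.0))
    assert np.allclose(sorted(geom.extents), sorted(spacing))
    assert vertebra_geometry(vol, None, 3) is None
    with pytest.raises(ValueError):
        vertebra_geometry(vol, None, 0)


def test_geometry_axes_match_eigendecomposition_oracle(small_sample):
    """Axes equal an explicit covariance eigen-decomposition of the
    voxel coordinate list."""
    geom = vertebra_geometry(small_sample.labels, None, 4)
    coords = np.argwhere(small_sample.labels.labels == 4) \
        * np.asarray(small_sample.labels.spacing)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    for i in range(3):
        assert abs(abs(geom.axes[i] @ evecs[:, order[i]]) - 1.0) < 1e-6
    assert np.allclose(geom.axes @ geom.axes.T, np.eye(3), atol=1e-6)


def test_geometry_mean_probability(small_sample):
    probs = np.zeros((8,) + small_sample.labels.shape, dtype=np.float32)
    probs[2] = 0.75
    geom = vertebra_geometry(small_sample.labels, probs, 2)
    assert geom.mean_prob == pytest.approx(0.75)


def test_geometry_recovers_phantom_body_size(small_sample):
    """Largest OBB extent of a phantom vertebra ~ its specified body
    diameter (the C3+ levels have no posterior ring)."""
    spec = small_sample.spec
    geom = vertebra_geometry(small_sample.labels, None, 5)
    diameter = 2 * max(spec.levels[4].radii)
    assert abs(max(geom.extents) - diameter) / diameter < 0.15
    centroid_err = np.abs(np.asarray(geom.centroid)
                          - np.asarray(spec.levels[4].center))
    assert np.all(centroid_err <= np.asarray(small_sample.ct.spacing) * 1.5)


def test_extract_roi_centering_and_constant():
    const = CTVolume(np.full((30, 30, 30), 300.0, dtype=np.float32),
                     spacing=(1, 1, 1))
    lab = np.zeros((30, 30, 30), dtype=np.int16)
    lab[10:20, 10:20, 12:18] = 1
    geom = vertebra_geometry(SegLabelVolume(lab, (1, 1, 1)), None, 1)
    roi = extract_roi(const, geom, (16, 16, 16), (1.0, 1.0, 1.0))
    assert roi.shape == (16, 16, 16)
    assert np.allclose(roi, 0.5, atol=1e-5)  # windowed 300 HU = 0.5

    # labeled voxels map to the ROI center
    ct = CTVolume(np.where(lab > 0, 900.0, -1000.0).astype(np.float32),
                  spacing=(1, 1, 1))
    roi2 = extract_roi(ct, geom, (16, 16, 16), (1.0, 1.0, 1.0))
    ctr = tuple(s // 2 for s in roi2.shape)
    assert roi2[ctr] == pytest.approx(0.9, abs=0.01)


def test_extract_roi_rotation_equivariance(small_sample):
    """Rotating the volume and geometry together by 90 deg about z leaves
    the ROI unchanged up to interpolation error."""
    ct = small_sample.ct
    geom = vertebra_geometry(small_sample.labels, None, 4)
    roi = extract_roi(ct, geom)

    # rotate 90 deg about z: (x, y) -> (y, X-1-x), an exact grid map
    vox_rot = np.rot90(ct.voxels, k=-1, axes=(0, 1)).copy()
    ct_rot = CTVolume(vox_rot, (ct.spacing[1], ct.spacing[0], ct.spacing[2]))
    nx = ct.shape[0]
    cx, cy, cz = geom.centroid
    rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    geom_rot = type(geom)(
        level=geom.level,
        centroid=(cy, (nx - 1) * ct.spacing[0] - cx, cz),
        axes=(rot.T @ geom.axes.T).T,
        extents=geom.extents, voxel_count=geom.voxel_count)
    roi_rot = extract_roi(ct_rot, geom_rot)
    assert np.abs(roi_rot - roi).mean() < 0.02
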