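"""Phantom generator: body catalogue, volume targets, gaps, determinism."""

import math

import numpy as np
import pytest

from mitoros.phantom import (
    LABEL_CELL,
    LABEL_HIGH,
    LABEL_ISF,
    PhantomConfig,
    generate_phantom,
    superellipsoid_volume,
)


def test_body_counts_and_labels(phantom0):
    assert len(phantom0.bodies) == 26
    assert sum(1 for b in phantom0.bodies if b.label == LABEL_HIGH) == 2
    assert sum(1 for b in phantom0.bodies if b.label == LABEL_CELL) == 24


def test_analytic_cell_fraction_hits_target(phantom0):
    assert phantom0.cell_fraction_analytic == pytest.approx(0.60, abs=0.01)
    # the voxelised fraction agrees with the analytic one
    vox = (phantom0.labels != LABEL_ISF).mean()
    assert vox == pytest.approx(phantom0.cell_fraction_analytic, abs=0.01)


def test_central_spheres_occupy_printed_fraction(phantom0):
    """Closed form: 2 * (4/3) pi r^3 / (16*17*19) = 4.83%."""
    expected = 2.0 * (4.0 / 3.0) * math.pi * 3.1 ** 3 / (16.0 * 17.0 * 19.0)
    assert expected == pytest.approx(0.0483, abs=2e-4)
    assert phantom0.high_fraction_analytic == pytest.approx(expected,
                                                            rel=1e-12)


def test_volume_weighted_mean_initial_concentration(phantom0):
    mean = phantom0.mean_initial_concentration(10.0, 5.0)
    assert mean == pytest.approx(0.6 * 10.0 + 0.4 * 5.0, abs=0.05)


def test_generation_is_deterministic_per_seed():
    a = generate_phantom(seed=3)
    b = generate_phantom(seed=3)
    assert np.array_equal(a.labels, b.labels)
    for ba, bb in zip(a.bodies, b.bodies):
        np.testing.assert_array_equal(ba.center, bb.center)
    c = generate_phantom(seed=4)
    assert not np.array_equal(a.labels, c.labels)


def test_bodies_keep_at_least_one_voxel_gap(phantom0):
    """Dilating each body's voxel mask by one voxel must not touch
    another body."""
    from scipy.ndimage import binary_dilation

    xs, ys, zs = phantom0.voxel_centers()
    X, Y, Z = xs[:, None, None], ys[None, :, None], zs[None, None, :]
    masks = [b.inside(X, Y, Z) for b in phantom0.bodies]
    all_bodies = np.zeros(phantom0.shape, dtype=bool)
    for m in masks:
        all_bodies |= m
    for m in masks:
        grown = binary_dilation(m)
        assert not np.any(grown & all_bodies & ~m)


def test_axis_passes_through_the_high_production_bodies(phantom0):
    xs, y, z = phantom0.axis_points()
    h = phantom0.voxel_um
    o = phantom0.origin_um
    j = int((y[0] - o[1]) / h)
    k = int((z[0] - o[2]) / h)
    labels = phantom0.labels[:, j, k]
    assert np.count_nonzero(labels == LABEL_HIGH) > 20


def test_superellipsoid_volume_reduces_to_sphere():
    v = superellipsoid_volume(1.3, 1.3, 1.3, 2.0)
    assert v == pytest.approx(4.0 / 3.0 * math.pi * 1.3 ** 3, rel=1e-12)


def test_voxel_size_must_divide_domain():
    with pytest.raises(ValueError, match="divide"):
        PhantomConfig(voxel_um=0.3)


def test_initial_concentration_by_label(phantom0):
    c = phantom0.initial_concentration(10.0, 5.0)
    assert np.all(c[phantom0.labels == LABEL_ISF] == 5.0)
    assert np.all(c[phantom0.labels != LABEL_ISF] == 10.0)
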