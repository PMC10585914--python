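"""Coordinate maps, Gaussian margins and sequential clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucseg import NetworkOutput
from nucseg.clustering import (
    ClusterParams,
    InstanceCenter,
    assign_pixel,
    compute_embeddings,
    gaussian_margin,
    instance_centroid,
    make_coordinate_map,
    sequential_cluster,
)


# ----------------------------------------------------------------- coords
def test_coordinate_map_2x2_convention():
    c = make_coordinate_map(2, 2)
    np.testing.assert_allclose(c[0], [[0.25, 0.75], [0.25, 0.75]])
    np.testing.assert_allclose(c[1], [[0.25, 0.25], [0.75, 0.75]])


def test_coordinate_map_single_pixel_is_center():
    np.testing.assert_allclose(make_coordinate_map(1, 1).ravel(), [0.5, 0.5])


def test_coordinate_map_matches_double_loop():
    h, w = 3, 5
    c = make_coordinate_map(h, w)
    for r in range(h):
        for col in range(w):
            assert c[0, r, col] == (col + 0.5) / w
            assert c[1, r, col] == (r + 0.5) / h
    assert (c > 0).all() and (c < 1).all()


def test_coordinate_map_rejects_bad_sizes():
    with pytest.raises(ValueError):
        make_coordinate_map(0, 5)


# -------------------------------------------------------------- embeddings
def test_embeddings_zero_offset_equal_coords():
    c = make_coordinate_map(4, 4)
    np.testing.assert_array_equal(compute_embeddings(np.zeros_like(c), c), c)


def test_embeddings_constant_offset_shift():
    c = make_coordinate_map(4, 4)
    off = np.zeros_like(c)
    off[0] = 0.1
    e = compute_embeddings(off, c)
    np.testing.assert_allclose(e[0], c[0] + 0.1)
    np.testing.assert_array_equal(e[1], c[1])


def test_embeddings_match_pixel_loop_and_reject_mismatch():
    rng = np.random.default_rng(0)
    c = make_coordinate_map(3, 4)
    off = rng.normal(0, 0.2, c.shape)
    e = compute_embeddings(off, c)
    for ch in range(2):
        for r in range(3):
            for col in range(4):
                assert e[ch, r, col] == c[ch, r, col] + off[ch, r, col]
    with pytest.raises(ValueError):
        compute_embeddings(off[:, :2], c)


# --------------------------------------------------------------- centroid
def test_centroid_single_pixel_and_symmetry():
    labels = np.zeros((4, 4), int)
    labels[1, 2] = 1
    c = make_coordinate_map(4, 4)
    assert instance_centroid(labels, c, 1) == (c[0, 1, 2], c[1, 1, 2])
    labels[:] = 0
    labels[1:3, 1:3] = 2  # mirror-symmetric block
    np.testing.assert_allclose(instance_centroid(labels, c, 2), (0.5, 0.5))


def test_centroid_matches_bruteforce_mean():
    rng = np.random.default_rng(1)
    labels = (rng.random((6, 7)) < 0.4).astype(int)
    labels[0, 0] = 1  # non-empty
    c = make_coordinate_map(6, 7)
    cx, cy = instance_centroid(labels, c, 1)
    pix = np.argwhere(labels == 1)
    assert cx == pytest.approx(np.mean([(p[1] + 0.5) / 7 for p in pix]))
    assert cy == pytest.approx(np.mean([(p[0] + 0.5) / 6 for p in pix]))
    with pytest.raises(ValueError):
        instance_centroid(labels, c, 99)


# ---------------------------------------------------------- gaussian margin
def test_gaussian_margin_analytic_values():
    ctr = InstanceCenter(cx=0.4, cy=0.6, sigma_x=0.05, sigma_y=0.08,
                         seed_value=1.0)
    assert gaussian_margin((0.4, 0.6), ctr) == pytest.approx(1.0, abs=1e-15)
    # half-margin point: offset sigma*sqrt(2 ln 2) along x
    dx = ctr.sigma_x * np.sqrt(2 * np.log(2))
    assert gaussian_margin((0.4 + dx, 0.6), ctr) == pytest.approx(0.5,
                                                                  abs=1e-12)
    # one-sigma along both axes
    val = gaussian_margin((0.4 + 0.05, 0.6 + 0.08), ctr)
    assert val == pytest.approx(np.exp(-1.0), abs=1e-12)


def test_gaussian_margin_rejects_nonpositive_sigma():
    with pytest.raises(ValueError):
        gaussian_margin((0, 0), InstanceCenter(0, 0, 0.0, 0.1, 1.0))


def test_assignment_threshold_boundary():
    assert assign_pixel(0.5) is True
    assert assign_pixel(0.499) is False
    assert assign_pixel(1.0) is True


# ------------------------------------------------------ sequential cluster
def _uniform_output(h, w, seed_map, offsets, sigma):
    return NetworkOutput(seed=seed_map[None] if seed_map.ndim == 2 else seed_map,
                         offsets=offsets, sigma=sigma)


def test_all_below_threshold_gives_empty_labels():
    h = w = 8
    out = _uniform_output(h, w, np.full((h, w), 0.2), np.zeros((2, h, w)),
                          np.full((2, h, w), 0.1))
    labels, centers = sequential_cluster(out, make_coordinate_map(h, w))
    assert labels.max() == 0 and centers == []


def _planted_two_instance_field(h=16, w=16):
    """Embeddings collapse onto two centroids; seed=1 on foreground."""
    truth = np.zeros((h, w), int)
    truth[3:8, 3:8] = 1
    truth[9:14, 9:14] = 2
    coords = make_coordinate_map(h, w)
    offsets = np.zeros((2, h, w))
    for k in (1, 2):
        m = truth == k
        cx, cy = coords[0][m].mean(), coords[1][m].mean()
        offsets[0][m] = cx - coords[0][m]
        offsets[1][m] = cy - coords[1][m]
    seed = np.where(truth > 0, 1.0, 0.0)
    sigma = np.full((2, h, w), 0.02)
    return truth, coords, NetworkOutput(seed[None], offsets, sigma)


def test_recovers_planted_two_instance_partition_exactly():
    truth, coords, out = _planted_two_instance_field()
    labels, centers = sequential_cluster(
        out, coords, ClusterParams(min_pixels=4)
    )
    assert len(centers) == 2
    # same partition up to label order
    for k in (1, 2):
        ids = np.unique(labels[truth == k])
        assert len(ids) == 1 and ids[0] > 0
    assert (labels[truth == 0] == 0).all()


def test_single_cluster_equals_exhaustive_phi_assignment():
    h = w = 12
    coords = make_coordinate_map(h, w)
    rng = np.random.default_rng(5)
    offsets = rng.normal(0, 0.03, (2, h, w))
    sigma = np.full((2, h, w), 0.15)
    seed = np.zeros((h, w))
    seed[6, 6] = 0.9  # the only pixel above threshold
    out = NetworkOutput(seed[None], offsets, sigma)
    labels, centers = sequential_cluster(out, coords,
                                         ClusterParams(min_pixels=1))
    assert len(centers) == 1
    c = centers[0]
    emb = compute_embeddings(offsets, coords)
    # oracle: exhaustive phi >= 0.5 evaluation
    expected = np.zeros((h, w), int)
    for r in range(h):
        for col in range(w):
            phi = gaussian_margin((emb[0, r, col], emb[1, r, col]), c)
            expected[r, col] = 1 if phi >= 0.5 else 0
    np.testing.assert_array_equal(labels, expected)


def test_min_pixels_discards_small_instances_but_keeps_pixels_assignable():
    h = w = 8
    coords = make_coordinate_map(h, w)
    seed = np.zeros((h, w))
    seed[2, 2] = 0.99  # isolated high seed with a tiny margin
    seed[5, 5] = 0.8
    offsets = np.zeros((2, h, w))
    sigma = np.full((2, h, w), 0.005)
    sigma[:, 5, 5] = 0.6  # large margin: second cluster reaches (2,2)
    out = NetworkOutput(seed[None], offsets, sigma)
    labels, centers = sequential_cluster(out, coords,
                                         ClusterParams(min_pixels=4))
    # first candidate (2,2) yields a single-pixel instance -> discarded;
    # second candidate absorbs the board including (2,2)
    assert len(centers) == 1
    assert labels[2, 2] == 1
    assert labels.max() == 1


def test_clustering_is_deterministic(small_scene):
    h, w = small_scene.labels.shape
    coords = make_coordinate_map(h, w)
    rng = np.random.default_rng(9)
    out = NetworkOutput(rng.random((1, h, w)),
                        rng.normal(0, 0.05, (2, h, w)),
                        np.full((2, h, w), 0.05))
    l1, _ = sequential_cluster(out, coords)
    l2, _ = sequential_cluster(out, coords)
    np.testing.assert_array_equal(l1, l2)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_labels_are_a_partition_with_contiguous_ids(seed):
    h = w = 10
    rng = np.random.default_rng(seed)
    out = NetworkOutput(rng.random((1, h, w)),
                        rng.normal(0, 0.1, (2, h, w)),
                        np.exp(rng.normal(-2.5, 0.5, (2, h, w))))
    labels, centers = sequential_cluster(
        out, make_coordinate_map(h, w), ClusterParams(min_pixels=2)
    )
    ids = np.unique(labels)
    ids = ids[ids > 0]
    np.testing.assert_array_equal(ids, np.arange(1, len(ids) + 1))
    assert len(centers) == len(ids)
    for i in ids:
        assert (labels == i).sum() >= 2
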