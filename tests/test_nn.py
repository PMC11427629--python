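import numpy as np
import pytest

from surfbind.autograd import ScatterIndex, Tensor
from surfbind.fixtures import fps_exhaustive, radial_graph_bruteforce
from surfbind.nn import (CGConv, ClassificationNet, LayerConfig,
                         SegmentationNet, build_hierarchy, build_radial_graph,
                         farthest_point_sample, global_attention_pool,
                         knn_unpool, load_checkpoint, save_checkpoint)

from conftest import random_cloud_mesh, random_rotation


# ---------------------------------------------------------------------------
# farthest point sampling


def test_fps_collinear_hand_example():
    V = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])
    idx = farthest_point_sample(V, ratio=0.5, start=0)
    assert list(idx) == [0, 7, 3, 5]


def test_fps_full_ratio_returns_everything():
    rng = np.random.default_rng(0)
    V = rng.normal(size=(17, 3))
    idx = farthest_point_sample(V, ratio=1.0, start=4)
    assert sorted(idx) == list(range(17))


def test_fps_coincident_points_no_crash():
    V = np.zeros((2, 3))
    idx = farthest_point_sample(V, ratio=0.5, start=0)
    assert list(idx) == [0]


def test_fps_empty_errors():
    with pytest.raises(ValueError):
        farthest_point_sample(np.zeros((0, 3)), ratio=0.5)


@pytest.mark.parametrize("seed", range(10))
def test_fps_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 80))
    V = rng.uniform(-5, 5, size=(n, 3))
    start = int(rng.integers(n))
    fast = farthest_point_sample(V, ratio=0.5, start=start)
    slow = fps_exhaustive(V, ratio=0.5, start=start)
    assert list(fast) == slow


# ---------------------------------------------------------------------------
# radial graph


def test_radial_graph_empty_when_radius_too_small():
    V = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0]], dtype=float)
    edges = build_radial_graph(V, np.array([0, 1]), radius=1.0)
    assert len(edges) == 0


def test_radial_graph_complete_when_everything_in_range():
    rng = np.random.default_rng(1)
    V = rng.uniform(0, 1, size=(12, 3))
    centroids = np.array([0, 5, 9])
    edges = build_radial_graph(V, centroids, radius=10.0)
    counts = np.bincount(edges[:, 1], minlength=3)
    assert np.all(counts == 11)


@pytest.mark.parametrize("seed", range(10))
def test_radial_graph_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    V = rng.uniform(-4, 4, size=(200, 3))
    centroids = rng.choice(200, size=40, replace=False)
    r = float(rng.uniform(1.0, 3.0))
    fast = {(int(a), int(b)) for a, b in build_radial_graph(V, centroids, r)}
    assert fast == radial_graph_bruteforce(V, centroids, r)


# ---------------------------------------------------------------------------
# CG convolution


def _conv_setup(n_edges, hidden=4, seed=0):
    rng = np.random.default_rng(seed)
    conv = CGConv(hidden, 4, rng)
    xc = Tensor(rng.normal(size=(2, hidden)))
    xs = Tensor(rng.normal(size=(5, hidden)))
    edges = np.column_stack([
        rng.integers(0, 5, n_edges), np.sort(rng.integers(0, 2, n_edges))
    ])
    ef = rng.normal(size=(n_edges, 4))
    return conv, xc, xs, edges, ef


def test_cgconv_zero_aggregation_weights_is_identity():
    conv, xc, xs, edges, ef = _conv_setup(6)
    conv.agg_w.data[:] = 0.0
    out = conv(xc, xs, edges, ef, 2)
    np.testing.assert_allclose(out.data, xc.data, atol=1e-12)


def test_cgconv_single_neighbor_statistics_degenerate():
    """With one incoming message min = max = mean and stdev ~ 0, so the
    update reduces to (w_min + w_max + w_mean) * message."""
    conv, xc, xs, _, _ = _conv_setup(1)
    edges = np.array([[2, 0]])
    ef = np.zeros((1, 4))
    conv.agg_w.data[:] = np.array([[1.0], [1.0], [1.0], [1.0]])
    out1 = conv(xc, xs, edges, ef, 2)
    conv.agg_w.data[:] = np.array([[3.0], [0.0], [0.0], [0.0]])
    out_min = conv(xc, xs, edges, ef, 2)
    # centroid 1 has no neighbors: passthrough in both cases
    np.testing.assert_allclose(out1.data[1], xc.data[1])
    np.testing.assert_allclose(out1.data[0], out_min.data[0], atol=1e-4)


def test_cgconv_no_edges_passthrough():
    conv, xc, xs, _, _ = _conv_setup(0)
    out = conv(xc, xs, np.zeros((0, 2), int), np.zeros((0, 4)), 2)
    np.testing.assert_allclose(out.data, xc.data)


def test_segment_statistics_of_opposite_messages():
    """Two messages m and -m: mean 0, stdev |m| elementwise (population)."""
    from surfbind.autograd import (segment_max, segment_mean, segment_min,
                                   sqrt, relu)

    m = np.array([[1.0, -2.0], [-1.0, 2.0]])
    x = Tensor(m)
    plan = ScatterIndex(np.array([0, 0]), 1)
    me = segment_mean(x, plan)
    m2 = segment_mean(x * x, plan)
    sd = sqrt(relu(m2 - me * me) + 1e-12)
    mn = segment_min(x, plan)
    mx = segment_max(x, plan)
    np.testing.assert_allclose(me.data, [[0.0, 0.0]], atol=1e-12)
    np.testing.assert_allclose(sd.data, [[1.0, 2.0]], atol=1e-5)
    np.testing.assert_allclose(mn.data, [[-1.0, -2.0]])
    np.testing.assert_allclose(mx.data, [[1.0, 2.0]])


# ---------------------------------------------------------------------------
# KNN unpooling


def test_unpool_coincident_vertex_copies_centroid():
    coarse_V = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [4, 4, 0.]])
    feats = np.arange(8.0).reshape(4, 2)
    fine_V = np.array([[4, 0, 0.]])
    out = knn_unpool(coarse_V, feats, fine_V, k=3)
    np.testing.assert_allclose(out[0], feats[1])


def test_unpool_equidistant_three_centroids_is_mean():
    coarse_V = np.array([[1, 0, 0], [-0.5, np.sqrt(3) / 2, 0],
                         [-0.5, -np.sqrt(3) / 2, 0], [50, 50, 50.]])
    feats = np.array([[3.0], [6.0], [9.0], [1000.0]])
    out = knn_unpool(coarse_V, feats, np.zeros((1, 3)), k=3)
    np.testing.assert_allclose(out[0, 0], 6.0, atol=1e-9)


def test_unpool_hand_weighted_value():
    # distances 1 and 3, feats 0 and 4, k=2 -> (1*0 + (1/3)*4) / (4/3) = 1.0
    coarse_V = np.array([[1, 0, 0], [-3, 0, 0.]])
    feats = np.array([[0.0], [4.0]])
    out = knn_unpool(coarse_V, feats, np.zeros((1, 3)), k=2)
    np.testing.assert_allclose(out[0, 0], 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# global attention pooling


def test_attention_pool_zero_gate_halves_sum():
    rng = np.random.default_rng(0)
    x = Tensor(rng.normal(size=(7, 5)))
    r = global_attention_pool(x, Tensor(np.zeros((7, 1))))
    np.testing.assert_allclose(r.data, 0.5 * x.data.sum(0, keepdims=True))


def test_attention_pool_closed_gate_vanishes():
    rng = np.random.default_rng(0)
    x = Tensor(rng.normal(size=(7, 5)))
    r = global_attention_pool(x, Tensor(np.full((7, 1), -1e3)))
    np.testing.assert_allclose(r.data, 0.0, atol=1e-12)


def test_attention_pool_permutation_invariant():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(9, 4))
    g = rng.normal(size=(9, 1))
    r0 = global_attention_pool(Tensor(x), Tensor(g)).data
    perm = rng.permutation(9)
    r1 = global_attention_pool(Tensor(x[perm]), Tensor(g[perm])).data
    np.testing.assert_allclose(r1, r0, atol=1e-6)


# ---------------------------------------------------------------------------
# network forward passes


@pytest.fixture(scope="module")
def cloud_setup():
    mesh = random_cloud_mesh(220, seed=5)
    rng = np.random.default_rng(6)
    X = rng.normal(size=(220, 18))
    hier = build_hierarchy(mesh, LayerConfig(hidden=8))
    return mesh, X, hier


def test_segmentation_rows_sum_to_one(cloud_setup):
    _, X, hier = cloud_setup
    net = SegmentationNet(18, LayerConfig(hidden=8), seed=0)
    probs = net.forward(hier, X).data
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert probs.shape == (220, 2)


def test_classification_probabilities_sum_to_one(cloud_setup):
    _, X, hier = cloud_setup
    net = ClassificationNet(18, LayerConfig(hidden=8), seed=0)
    probs = net.forward(hier, X).data
    assert probs.shape == (1, 2)
    np.testing.assert_allclose(probs.sum(), 1.0, atol=1e-6)


@pytest.mark.parametrize("net_cls,tol_perm,tol_rigid",
                         [(SegmentationNet, 1e-6, 1e-4),
                          (ClassificationNet, 1e-6, 1e-4)])
def test_forward_isometry_and_permutation_invariance(cloud_setup, net_cls,
                                                     tol_perm, tol_rigid):
    """The central symmetry property: outputs depend only on distances,
    angles, and invariant vertex features."""
    mesh, X, hier = cloud_setup
    net = net_cls(18, LayerConfig(hidden=8), seed=3)
    p0 = net.forward(hier, X).data

    rng = np.random.default_rng(11)
    Q = random_rotation(rng)
    moved = mesh.transformed(Q, rng.uniform(-30, 30, 3))
    p_rigid = net.forward(build_hierarchy(moved, LayerConfig(hidden=8)), X).data
    np.testing.assert_allclose(p_rigid, p0, atol=tol_rigid)

    perm = rng.permutation(mesh.n_vertices)
    permuted = type(mesh)(mesh.V[perm], np.zeros((0, 3), int))
    permuted.normals = mesh.normals[perm]
    p_perm = net.forward(build_hierarchy(permuted, LayerConfig(hidden=8)),
                         X[perm]).data
    if net_cls is SegmentationNet:
        np.testing.assert_allclose(p_perm, p0[perm], atol=tol_perm)
    else:
        np.testing.assert_allclose(p_perm, p0, atol=tol_perm)


def test_feature_count_mismatch_raises(cloud_setup):
    _, X, hier = cloud_setup
    net = SegmentationNet(18, LayerConfig(hidden=8), seed=0)
    with pytest.raises(ValueError, match="expects"):
        net.forward(hier, X[:, :6])


def test_gradient_reaches_input_layer(cloud_setup):
    """Skip connections keep gradient flowing to the first layer."""
    _, X, hier = cloud_setup
    net = SegmentationNet(18, LayerConfig(hidden=8), seed=0)
    probs = net.forward(hier, X)
    probs.slice_cols(1, 2).mean().backward()
    assert net.lin_in.W.grad is not None
    assert np.linalg.norm(net.lin_in.W.grad) > 0


def test_checkpoint_round_trip_bit_stable(tmp_path, cloud_setup):
    _, X, hier = cloud_setup
    net = ClassificationNet(18, LayerConfig(hidden=8), seed=9)
    p0 = net.forward(hier, X).data
    path = str(tmp_path / "model.npz")
    save_checkpoint(net, path, extra={"note": "test"})
    again, extra = load_checkpoint(path)
    assert extra["note"] == "test"
    for a, b in zip(net.params(), again.params()):
        np.testing.assert_array_equal(a.data, b.data)
    np.testing.assert_array_equal(again.forward(hier, X).data, p0)


def test_layer_config_validation():
    with pytest.raises(ValueError):
        LayerConfig(radii=(5.0, 7.5))
    with pytest.raises(ValueError):
        LayerConfig(radii=(5.0, 5.0, 4.0))
    with pytest.raises(ValueError):
        LayerConfig(ratio=1.5)
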