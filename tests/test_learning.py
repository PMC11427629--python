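import numpy as np
import pytest

from surfbind.autograd import Tensor
from surfbind.fixtures import (PlantedDatasetSpec, make_planted_dataset,
                               make_toy_structure, planted_graph_samples)
from surfbind.learning import (TrainConfig, cross_entropy, crossval_ensemble,
                               ensemble_predict, label_binding, metrics,
                               platt_apply, platt_scale, residue_pool,
                               select_threshold_max_f1, train)
from surfbind.nn import LayerConfig


# ---------------------------------------------------------------------------
# cross-entropy


def test_perfect_fit_loss_near_zero():
    q = np.array([1.0, 0.0, 1.0])
    p = np.array([1, 0, 1])
    assert cross_entropy(q, p) < 1e-6


def test_uniform_prediction_gives_ln2():
    q = np.full(10, 0.5)
    p = np.array([1, 0] * 5)
    assert cross_entropy(q, p) == pytest.approx(np.log(2.0))


def test_hand_computed_loss():
    # -(ln 0.9 + ln 0.8) / 2 ~ 0.16425
    got = cross_entropy(np.array([0.9, 0.2]), np.array([1, 0]))
    assert got == pytest.approx(-(np.log(0.9) + np.log(0.8)) / 2, abs=1e-9)
    assert got == pytest.approx(0.1643, abs=5e-4)


def test_objective_matches_termwise_hand_sum():
    """Three-vertex check of the displayed objective
    -sum_i [p_i log q_i + (1 - p_i) log(1 - q_i)], mean-reduced."""
    q = np.array([0.7, 0.4, 0.95])
    p = np.array([1, 0, 1])
    by_hand = -(np.log(0.7) + np.log(0.6) + np.log(0.95)) / 3.0
    assert cross_entropy(q, p) == pytest.approx(by_hand, abs=1e-12)


def test_tensor_path_matches_numpy_path_and_differentiates():
    q = Tensor(np.array([[0.7], [0.4], [0.95]]), requires_grad=True)
    p = np.array([1, 0, 1])
    loss = cross_entropy(q, p)
    assert loss.data == pytest.approx(cross_entropy(q.data.ravel(), p))
    loss.backward()
    # d/dq of -[p log q + (1-p) log(1-q)] / n = (q - p) / (q (1-q) n)
    expect = (q.data.ravel() - p) / (q.data.ravel() * (1 - q.data.ravel()) * 3)
    np.testing.assert_allclose(q.grad.ravel(), expect, atol=1e-9)


def test_shape_mismatch_raises():
    with pytest.raises(ValueError):
        cross_entropy(np.array([0.5, 0.5]), np.array([1, 0, 1]))


# ---------------------------------------------------------------------------
# binding labels


def test_residue_within_cutoff_labeled():
    structure, na = make_toy_structure(6, seed=0, na_offset=4.9, na_residue=2)
    labels = label_binding(structure, na, cutoff=5.0)
    assert labels.residue_labels[2] == 1


def test_empty_na_set_all_zero():
    structure, _ = make_toy_structure(5, seed=0)
    labels = label_binding(structure, np.zeros((0, 3)))
    assert labels.residue_labels.sum() == 0
    assert labels.mesh_label == 0


def test_distance_thresholding_exact():
    """Residues 3, 6, and 10 A from one NA atom -> labels 1/0/0 at 5.0 A."""
    from surfbind.structure import Atom, AtomicStructure

    atoms = [
        Atom(i + 1, "CA", "C", "ALA", i + 1, "A", float(x), 0.0, 0.0,
             radius=1.7)
        for i, x in enumerate([3.0, 6.0, 10.0])
    ]
    labels = label_binding(AtomicStructure(atoms), np.zeros((1, 3)))
    assert list(labels.residue_labels) == [1, 0, 0]


def test_vertex_labels_inherit_residue(toy_structure):
    structure, na = toy_structure
    vr = np.array([0, 0, 3, 3, 5])
    labels = label_binding(structure, na, vertex_residue=vr)
    expect = labels.residue_labels[vr]
    np.testing.assert_array_equal(labels.vertex_labels, expect)


# ---------------------------------------------------------------------------
# Platt scaling


def test_platt_recovers_known_parameters():
    """Mean over seeded n=500 replicates recovers the generating sigmoid;
    averaging suppresses the MLE's own sampling noise."""
    a0, b0 = 2.5, -1.0
    fits = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=500)
        p = 1.0 / (1.0 + np.exp(-(a0 * s + b0)))
        y = (rng.random(500) < p).astype(int)
        fits.append(platt_scale(s, y))
    a, b = np.mean(fits, axis=0)
    assert a == pytest.approx(a0, rel=0.10)
    assert b == pytest.approx(b0, rel=0.10)


def test_platt_preserves_ranking():
    rng = np.random.default_rng(1)
    s = rng.normal(size=200)
    y = (s + rng.normal(scale=0.5, size=200) > 0).astype(int)
    a, b = platt_scale(s, y)
    calibrated = platt_apply(np.sort(s), a, b)
    assert np.all(np.diff(calibrated) >= 0)


def test_platt_symmetric_scores_give_symmetric_calibration():
    rng = np.random.default_rng(2)
    s = rng.normal(size=1000)
    p = 1.0 / (1.0 + np.exp(-3 * s))
    y = (rng.random(1000) < p).astype(int)
    a, b = platt_scale(s, y)
    for delta in (0.1, 0.3, 0.7):
        total = platt_apply(-delta, a, b) + platt_apply(delta, a, b)
        assert abs(total - 1.0) < 0.05


def test_platt_single_class_errors():
    with pytest.raises(ValueError):
        platt_scale(np.array([0.1, 0.9]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# threshold selection


def test_max_f1_threshold_hand_example():
    tau = select_threshold_max_f1(np.array([0.9, 0.8, 0.2]),
                                  np.array([1, 1, 0]))
    assert tau == pytest.approx(0.8)


def test_inverted_scores_fall_back_to_min_threshold():
    probs = np.array([0.1, 0.2, 0.9, 0.8])
    labels = np.array([1, 1, 0, 0])
    tau = select_threshold_max_f1(probs, labels)
    # best F1 is the predict-everything-positive threshold
    assert tau == pytest.approx(probs.min())


def test_all_positive_labels_min_threshold():
    probs = np.array([0.3, 0.6, 0.9])
    tau = select_threshold_max_f1(probs, np.array([1, 1, 1]))
    assert tau == pytest.approx(0.3)


def test_threshold_matches_exhaustive_scan():
    rng = np.random.default_rng(3)
    probs = rng.random(60)
    labels = (rng.random(60) < probs).astype(int)

    def f1_at(t):
        pred = probs >= t
        tp = (pred & (labels == 1)).sum()
        fp = (pred & (labels == 0)).sum()
        fn = (~pred & (labels == 1)).sum()
        return 2 * tp / max(2 * tp + fp + fn, 1)

    tau = select_threshold_max_f1(probs, labels)
    best = max(f1_at(t) for t in probs)
    assert f1_at(tau) == pytest.approx(best)


# ---------------------------------------------------------------------------
# residue pooling


def test_residue_max_pooling():
    probs = np.array([0.1, 0.7, 0.3, 0.2])
    vr = np.array([0, 0, 0, 1])
    res, mask = residue_pool(probs, vr, n_residues=3)
    assert res[0] == pytest.approx(0.7)
    assert res[1] == pytest.approx(0.2)
    assert not mask[2] and np.isnan(res[2])  # buried residue flagged


def test_single_residue_takes_global_max():
    probs = np.array([0.15, 0.65, 0.4])
    res, mask = residue_pool(probs, np.zeros(3, dtype=int), n_residues=1)
    assert res[0] == pytest.approx(0.65)
    assert mask.all()


# ---------------------------------------------------------------------------
# metrics


def test_auroc_hand_example():
    out = metrics(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
    assert out["AUROC"] == pytest.approx(0.75)


def test_perfect_confusion_metrics():
    probs = np.array([0.9, 0.8, 0.1])
    labels = np.array([1, 1, 0])
    out = metrics(probs, labels, threshold=0.5)
    assert out["MCC"] == pytest.approx(1.0)
    assert out["BA"] == pytest.approx(1.0)
    assert out["FPR"] == 0.0


def test_random_scores_auroc_half():
    rng = np.random.default_rng(4)
    probs = rng.random(10_000)
    labels = np.array([0, 1] * 5_000)
    out = metrics(probs, labels)
    assert out["AUROC"] == pytest.approx(0.5, abs=0.02)


def test_one_class_rank_metrics_absent():
    out = metrics(np.array([0.2, 0.9]), np.array([1, 1]))
    assert "AUROC" not in out and "AUPRC" not in out
    assert out["recall"] == 0.5  # one of two positives above threshold


# ---------------------------------------------------------------------------
# training


@pytest.fixture(scope="module")
def tiny_planted():
    spec = PlantedDatasetSpec(n_meshes=8, subdivisions=2, sphere_radius=16.0,
                              patch_radius=15.0, seed=21)
    return planted_graph_samples(make_planted_dataset(spec),
                                 LayerConfig(hidden=8))


def test_two_epoch_smoke_loss_decreases(tiny_planted):
    cfg = TrainConfig(lr=5e-3, batch=4, max_epochs=2, patience=5, seed=0)
    _, info = train(tiny_planted, "segmentation", LayerConfig(hidden=8), cfg)
    h = info["history"]
    assert len(h) == 2
    assert info["best_val_loss"] <= h[0]["val_loss"] + 1e-12


def test_training_deterministic_under_seed(tiny_planted):
    cfg = TrainConfig(lr=5e-3, batch=4, max_epochs=2, patience=5, seed=7)
    m1, i1 = train(tiny_planted, "segmentation", LayerConfig(hidden=8), cfg)
    m2, i2 = train(tiny_planted, "segmentation", LayerConfig(hidden=8), cfg)
    assert i1["best_val_loss"] == pytest.approx(i2["best_val_loss"], abs=1e-6)
    for a, b in zip(m1.params(), m2.params()):
        np.testing.assert_allclose(a.data, b.data, atol=1e-10)


def test_single_class_dataset_rejected(tiny_planted):
    import copy

    from surfbind.learning import LabelSet

    clones = []
    for s in tiny_planted[:4]:
        c = copy.copy(s)
        c.labels = LabelSet(vertex_labels=np.zeros_like(s.labels.vertex_labels),
                            mesh_label=0)
        clones.append(c)
    with pytest.raises(ValueError, match="single class"):
        train(clones, "segmentation", LayerConfig(hidden=8), TrainConfig())


def test_empty_dataset_rejected():
    with pytest.raises(ValueError):
        train([], "segmentation")


# ---------------------------------------------------------------------------
# cross-validation ensemble


@pytest.fixture(scope="module")
def tiny_classification():
    spec = PlantedDatasetSpec(n_meshes=20, subdivisions=2, sphere_radius=16.0,
                              patch_radius=15.0, seed=22,
                              task="classification", effect_size=3.0)
    return planted_graph_samples(make_planted_dataset(spec),
                                 LayerConfig(hidden=8))


def test_folds_partition_dataset(tiny_classification):
    cfg = TrainConfig(lr=5e-3, batch=4, max_epochs=2, patience=2, seed=0)
    ensemble = crossval_ensemble(tiny_classification, "classification", k=5,
                                 replicates=1, layer_config=LayerConfig(hidden=8),
                                 train_cfg=cfg)
    assert len(ensemble) == 5
    assert sorted(m.fold for m in ensemble) == list(range(5))
    assert all(m.threshold == 0.5 for m in ensemble)


def test_identical_members_equal_single_model(tiny_classification):
    cfg = TrainConfig(lr=5e-3, batch=4, max_epochs=1, patience=1, seed=0)
    ensemble = crossval_ensemble(tiny_classification[:10], "classification",
                                 k=2, replicates=1,
                                 layer_config=LayerConfig(hidden=8),
                                 train_cfg=cfg)
    clones = [ensemble[0], ensemble[0], ensemble[0]]
    s = tiny_classification[0]
    mean_prob, votes = ensemble_predict(clones, s.hierarchy, s.X)
    single = clones[0].predict_proba(s.hierarchy, s.X)
    np.testing.assert_allclose(mean_prob, single, atol=1e-12)


def test_ensemble_mean_probability_in_unit_interval(tiny_classification):
    cfg = TrainConfig(lr=5e-3, batch=4, max_epochs=1, patience=1, seed=1)
    ensemble = crossval_ensemble(tiny_classification[:10], "classification",
                                 k=2, replicates=2,
                                 layer_config=LayerConfig(hidden=8),
                                 train_cfg=cfg)
    for s in tiny_classification[10:12]:
        mean_prob, _ = ensemble_predict(ensemble, s.hierarchy, s.X)
        assert np.all((mean_prob >= 0) & (mean_prob <= 1))
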