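"""The probabilistic binding model: labels, loss, training, calibration.

Per-vertex (segmentation) or per-mesh (classification) labels are Bernoulli;
parameters minimize the cross-entropy between predicted probabilities ``q``
and observed labels ``p`` summed over graphs and vertices.  Training uses
Adam with early stopping on validation loss; an ensemble keeps the best of
several randomly initialized replicates per cross-validation fold, applies
Platt scaling per model on its validation fold, and thresholds per model at
the maximum-F1 point of training-set predictions (segmentation) or a fixed
0.5 (classification, where datasets are balanced).  Residue-level
probabilities are obtained by max pooling the vertex probabilities of each
residue's surface patch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .autograd import Tensor, log as ag_log
from .nn import (ClassificationNet, GraphHierarchy, LayerConfig,
                 SegmentationNet)
from .structure import AtomicStructure

logger = logging.getLogger("surfbind")

__all__ = [
    "LabelSet", "TrainConfig", "CalibratedModel", "PredictionResult",
    "GraphSample", "cross_entropy", "label_binding", "train", "adam_step",
    "crossval_ensemble", "platt_scale", "platt_apply",
    "select_threshold_max_f1", "residue_pool", "metrics",
]

_EPS = 1e-7


@dataclass
class LabelSet:
    """Binary labels for one structure: per-vertex, per-residue, or per-mesh."""

    vertex_labels: np.ndarray | None = None   # (N,) in {0,1}
    residue_labels: np.ndarray | None = None  # (R,) in {0,1}
    mesh_label: int | None = None

    @property
    def positive_fraction(self) -> float:
        if self.vertex_labels is not None:
            return float(self.vertex_labels.mean())
        if self.residue_labels is not None:
            return float(self.residue_labels.mean())
        return float(self.mesh_label)


@dataclass
class GraphSample:
    """One training item: precomputed hierarchy + features + labels."""

    hierarchy: GraphHierarchy
    X: np.ndarray
    labels: LabelSet
    vertex_residue: np.ndarray | None = None


@dataclass
class TrainConfig:
    lr: float = 5e-3
    batch: int = 4
    max_epochs: int = 60
    patience: int = 10
    seed: int = 0
    val_fraction: float = 0.2
    verbose: bool = False


@dataclass
class CalibratedModel:
    """A trained network with Platt parameters and a decision threshold."""

    model: SegmentationNet | ClassificationNet
    platt: tuple[float, float] = (1.0, 0.0)   # (a, b): sigmoid(a * s + b)
    threshold: float = 0.5
    fold: int = -1

    def predict_proba(self, hier: GraphHierarchy, X: np.ndarray) -> np.ndarray:
        raw = self.model.forward(hier, X).data[:, 1]
        return platt_apply(raw, *self.platt)


@dataclass
class PredictionResult:
    vertex_probs: np.ndarray | None = None
    vertex_labels: np.ndarray | None = None
    residue_probs: np.ndarray | None = None
    residue_mask: np.ndarray | None = None    # residues with surface vertices
    mesh_prob: float | None = None
    threshold: float = 0.5


# ---------------------------------------------------------------------------
# loss and labels


def cross_entropy(q, p) -> Tensor | float:
    """Mean binary cross-entropy ``-[p log q + (1-p) log(1-q)]``.

    ``q`` may be a Tensor (differentiable path) or an array; probabilities
    are clamped to ``[1e-7, 1 - 1e-7]``.
    """
    p = np.asarray(p, dtype=float).ravel()
    if isinstance(q, Tensor):
        if q.data.ravel().shape != p.shape:
            raise ValueError("shape mismatch between q and p")
        n = q.data.size
        q1 = q.reshape(-1, 1)
        # clamp by composition: clip has zero grad outside, emulate via data clip
        q1.data = np.clip(q1.data, _EPS, 1.0 - _EPS)
        pt = Tensor(p.reshape(-1, 1))
        loss = -(pt * ag_log(q1) + (1.0 - pt) * ag_log(1.0 - q1)).sum() / float(n)
        return loss
    q = np.clip(np.asarray(q, dtype=float).ravel(), _EPS, 1.0 - _EPS)
    if q.shape != p.shape:
        raise ValueError("shape mismatch between q and p")
    return float(-(p * np.log(q) + (1 - p) * np.log(1 - q)).mean())


def label_binding(structure: AtomicStructure, na_atoms: np.ndarray,
                  cutoff: float = 5.0,
                  vertex_residue: np.ndarray | None = None) -> LabelSet:
    """Distance labeling: a residue is positive iff any of its atoms lies
    within ``cutoff`` (default 5.0 A) of any nucleic-acid atom; vertices
    inherit their residue's label."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n_res = structure.n_residues
    res_labels = np.zeros(n_res, dtype=int)
    na_atoms = np.asarray(na_atoms, dtype=float).reshape(-1, 3)
    if len(na_atoms):
        tree = cKDTree(na_atoms)
        d, _ = tree.query(structure.coords)
        hit = d <= cutoff
        res_labels[np.unique(structure.residue_index[hit])] = 1
    vl = None
    if vertex_residue is not None:
        vl = res_labels[vertex_residue]
    return LabelSet(vertex_labels=vl, residue_labels=res_labels,
                    mesh_label=int(res_labels.any()))


# ---------------------------------------------------------------------------
# optimization


def adam_step(params: list[Tensor], state: dict, lr: float,
              beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
    state["t"] = state.get("t", 0) + 1
    t = state["t"]
    for i, p in enumerate(params):
        if p.grad is None:
            continue
        m = state.setdefault(f"m{i}", np.zeros_like(p.data))
        v = state.setdefault(f"v{i}", np.zeros_like(p.data))
        m *= beta1
        m += (1 - beta1) * p.grad
        v *= beta2
        v += (1 - beta2) * p.grad ** 2
        mhat = m / (1 - beta1 ** t)
        vhat = v / (1 - beta2 ** t)
        p.data = p.data - lr * mhat / (np.sqrt(vhat) + eps)


def _sample_loss(model, sample: GraphSample) -> Tensor:
    probs = model.forward(sample.hierarchy, sample.X)
    if model.kind == "segmentation":
        q = probs.slice_cols(1, 2)
        return cross_entropy(q, sample.labels.vertex_labels)
    q = probs.slice_cols(1, 2)
    return cross_entropy(q, np.array([sample.labels.mesh_label]))


def _dataset_loss(model, samples: list[GraphSample]) -> float:
    tot = 0.0
    for s in samples:
        q = model.forward(s.hierarchy, s.X).data[:, 1]
        if model.kind == "segmentation":
            tot += cross_entropy(q, s.labels.vertex_labels)
        else:
            tot += cross_entropy(q, np.array([s.labels.mesh_label]))
    return tot / max(len(samples), 1)


def _labels_of(samples: list[GraphSample], kind: str) -> np.ndarray:
    if kind == "segmentation":
        return np.concatenate([s.labels.vertex_labels for s in samples])
    return np.array([s.labels.mesh_label for s in samples])


def train(dataset: list[GraphSample], task: str = "segmentation",
          layer_config: LayerConfig | None = None,
          train_cfg: TrainConfig | None = None,
          val_set: list[GraphSample] | None = None):
    """Train a network on precomputed graph samples.

    Splits off a validation subset when none is given, minimizes the
    cross-entropy with Adam in mini-batches of meshes, early-stops on
    validation loss, and returns the model restored to its best-validation
    parameters together with the per-epoch loss history.  Deterministic for
    a fixed ``train_cfg.seed``.
    """
    if not dataset:
        raise ValueError("empty dataset")
    cfg = train_cfg or TrainConfig()
    lc = layer_config or LayerConfig()
    y_all = _labels_of(dataset, task)
    if len(np.unique(y_all)) < 2:
        raise ValueError("dataset contains a single class")
    rng = np.random.default_rng(cfg.seed)
    if val_set is None:
        idx = rng.permutation(len(dataset))
        n_val = max(1, int(round(cfg.val_fraction * len(dataset))))
        val_set = [dataset[i] for i in idx[:n_val]]
        train_set = [dataset[i] for i in idx[n_val:]]
        if len(train_set) == 0:
            train_set, val_set = list(dataset), list(dataset)
    else:
        train_set = list(dataset)

    n_feat = dataset[0].X.shape[1]
    net_cls = SegmentationNet if task == "segmentation" else ClassificationNet
    model = net_cls(n_feat, lc, seed=int(rng.integers(2 ** 31 - 1)))
    params = model.params()
    state: dict = {}
    best_val = np.inf
    best_data = [p.data.copy() for p in params]
    best_epoch = -1
    history: list[dict] = []
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_set))
        ep_loss = 0.0
        for b0 in range(0, len(order), cfg.batch):
            batch = [train_set[i] for i in order[b0:b0 + cfg.batch]]
            losses = [_sample_loss(model, s) for s in batch]
            total = losses[0]
            for ls in losses[1:]:
                total = total + ls
            total = total / float(len(batch))
            total.backward()
            adam_step(params, state, cfg.lr)
            ep_loss += total.data.item() * len(batch)
            for p in params:
                p.grad = None
        val_loss = _dataset_loss(model, val_set)
        history.append({"epoch": epoch, "train_loss": ep_loss / len(train_set),
                        "val_loss": val_loss})
        if cfg.verbose:
            logger.info("epoch %d train %.4f val %.4f", epoch,
                        history[-1]["train_loss"], val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_epoch = epoch
            best_data = [p.data.copy() for p in params]
            stale = 0
        else:
            stale += 1
            if stale > cfg.patience:
                break
    for p, d in zip(params, best_data):
        p.data = d
    return model, {"history": history, "best_val_loss": best_val,
                   "best_epoch": best_epoch}


# ---------------------------------------------------------------------------
# calibration / thresholding


def platt_scale(scores: np.ndarray, labels: np.ndarray,
                max_iter: int = 200) -> tuple[float, float]:
    """Fit ``p = sigmoid(a * s + b)`` by Newton iteration with Platt's
    regularized targets ``(N+ + 1)/(N+ + 2)`` and ``1/(N- + 2)``.

    The slope is constrained positive (order-preserving calibration).
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for Platt scaling")
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    t = np.where(y > 0.5, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    a, b = 1.0, 0.0
    for _ in range(max_iter):
        z = np.clip(a * s + b, -60, 60)
        p = 1.0 / (1.0 + np.exp(-z))
        g = p - t
        ga, gb = (g * s).sum(), g.sum()
        w = np.maximum(p * (1 - p), 1e-10)
        haa, hab, hbb = (w * s * s).sum(), (w * s).sum(), w.sum()
        det = haa * hbb - hab * hab
        if det < 1e-12:
            break
        da = (hbb * ga - hab * gb) / det
        db = (haa * gb - hab * ga) / det
        a, b = a - da, b - db
        if abs(da) + abs(db) < 1e-10:
            break
    if a <= 0:  # refuse order-reversing calibration
        a = 1e-6
    return float(a), float(b)


def platt_apply(scores: np.ndarray, a: float, b: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(a * np.asarray(scores) + b, -60, 60)))


def select_threshold_max_f1(probs: np.ndarray, labels: np.ndarray) -> float:
    """Threshold from the candidate set of unique predicted probabilities
    maximizing F1; ties resolve to the largest threshold."""
    p = np.asarray(probs, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    best_f1, best_t = -1.0, float(p.min())
    for t in np.unique(p):
        pred = p >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        fn = int((~pred & (y == 1)).sum())
        f1 = 2 * tp / max(2 * tp + fp + fn, 1)
        if f1 >= best_f1:  # >= keeps the largest tied threshold (ascending scan)
            best_f1, best_t = f1, float(t)
    return best_t


def residue_pool(vertex_probs: np.ndarray, vertex_residue: np.ndarray,
                 n_residues: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Max-pool vertex probabilities per residue.

    Returns ``(residue_probs, surface_mask)``; residues with no surface
    vertices are flagged buried (mask False, probability NaN).
    """
    vertex_probs = np.asarray(vertex_probs, dtype=float)
    vertex_residue = np.asarray(vertex_residue, dtype=int)
    n = int(vertex_residue.max()) + 1 if n_residues is None else n_residues
    out = np.full(n, -np.inf)
    np.maximum.at(out, vertex_residue, vertex_probs)
    mask = np.zeros(n, dtype=bool)
    mask[np.unique(vertex_residue)] = True
    out[~mask] = np.nan
    return out, mask


# ---------------------------------------------------------------------------
# metrics


def metrics(probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict:
    """Standard binary metrics; rank metrics use midrank tie handling and
    are reported absent for one-class inputs."""
    from sklearn.metrics import average_precision_score, roc_auc_score

    p = np.asarray(probs, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    out: dict[str, float] = {}
    if len(np.unique(y)) == 2:
        out["AUROC"] = float(roc_auc_score(y, p))
        out["AUPRC"] = float(average_precision_score(y, p))
    recall = tp / max(tp + fn, 1)
    precision = tp / max(tp + fp, 1)
    specificity = tn / max(tn + fp, 1)
    out["recall"] = recall
    out["precision"] = precision
    out["specificity"] = specificity
    out["BA"] = 0.5 * (recall + specificity)
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out["MCC"] = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    out["FPR"] = fp / max(fp + tn, 1)
    return out


# ---------------------------------------------------------------------------
# cross-validated ensemble


def crossval_ensemble(dataset: list[GraphSample], task: str = "segmentation",
                      k: int = 5, replicates: int = 1,
                      layer_config: LayerConfig | None = None,
                      train_cfg: TrainConfig | None = None) -> list[CalibratedModel]:
    """K-fold cross-validation with best-replicate-per-fold selection.

    Folds are stratified on the mesh label (or on patch presence for
    segmentation).  Within each fold, ``replicates`` models are trained from
    different random initializations and the one with the lowest validation
    loss is kept; Platt parameters are fitted on that model's validation
    fold and the decision threshold maximizes F1 on its training split
    (segmentation) or is fixed at 0.5 (classification).
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    cfg = train_cfg or TrainConfig()
    strat = np.array([
        s.labels.mesh_label if s.labels.mesh_label is not None
        else int(s.labels.vertex_labels.any()) for s in dataset
    ])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    ensemble: list[CalibratedModel] = []
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(dataset)), strat)):
        train_set = [dataset[i] for i in tr]
        val_set = [dataset[i] for i in va]
        best = None
        for rep in range(replicates):
            rep_cfg = TrainConfig(**{**cfg.__dict__,
                                     "seed": cfg.seed + 1000 * fold + rep})
            model, info = train(train_set, task, layer_config, rep_cfg,
                                val_set=val_set)
            if best is None or info["best_val_loss"] < best[1]:
                best = (model, info["best_val_loss"])
        model = best[0]
        val_scores = np.concatenate(
            [model.forward(s.hierarchy, s.X).data[:, 1] for s in val_set]
        )
        val_labels = _labels_of(val_set, task)
        if task == "segmentation" and len(np.unique(val_labels)) == 2:
            a, b = platt_scale(val_scores, val_labels)
            tr_scores = np.concatenate(
                [platt_apply(model.forward(s.hierarchy, s.X).data[:, 1], a, b)
                 for s in train_set]
            )
            tau = select_threshold_max_f1(tr_scores, _labels_of(train_set, task))
        else:
            a, b, tau = 1.0, 0.0, 0.5
        ensemble.append(CalibratedModel(model, (a, b), tau, fold))
    return ensemble


def ensemble_predict(ensemble: list[CalibratedModel], hier: GraphHierarchy,
                     X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean calibrated probability and majority-vote labels across members
    (each member thresholds with its own tau)."""
    probs = np.stack([m.predict_proba(hier, X) for m in ensemble])
    votes = np.stack([(p >= m.threshold) for p, m in zip(probs, ensemble)])
    return probs.mean(axis=0), (votes.mean(axis=0) >= 0.5).astype(int)
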