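"""Graph network building blocks and the two network assemblies.

The encoder shared by both networks coarsens the surface mesh ``d = 3``
times.  At each level a subset of vertices is chosen by farthest-point
sampling (ratio ``alpha = 0.5``); a directed radial graph joins every vertex
within ``r`` of a centroid to that centroid (``r = 5.0, 7.5, 10.0`` A per
level); two crystal-graph (gated, edge-conditioned) convolutions update the
centroid activations, aggregating messages by a learned linear combination
of min/max/mean/stdev pooling plus a residual; the centroids then become the
vertex set of the next level.

For segmentation the decoder interpolates back to full resolution with
distance-weighted k = 3 nearest-centroid unpooling and concatenated skip
connections (graph U-Net); for classification a single global attention
pooling ``r = sum_i sigma(f(x_i)) x_i`` aggregates the coarsest level.

Because every input to the networks (vertex features, edge lengths and
normal angles) is invariant under rigid motions, and every aggregation is
permutation-invariant with geometry-canonical sampling, the forward passes
are invariant to all isometries of Euclidean space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from . import autograd as ag
from .autograd import Tensor
from .mesh import SurfaceMesh, edge_geometry

__all__ = [
    "LayerConfig", "farthest_point_sample", "build_radial_graph",
    "knn_interpolation_matrix", "knn_unpool", "CGConv", "Linear",
    "global_attention_pool", "GraphHierarchy", "build_hierarchy",
    "SegmentationNet", "ClassificationNet", "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class LayerConfig:
    """Architecture hyperparameters (defaults follow the published design)."""

    depth: int = 3
    radii: tuple[float, ...] = (5.0, 7.5, 10.0)
    ratio: float = 0.5
    k_unpool: int = 3
    convs_per_layer: int = 2
    hidden: int = 32

    def __post_init__(self) -> None:
        if len(self.radii) != self.depth:
            raise ValueError("need one radius per layer")
        if any(b <= a for a, b in zip(self.radii, self.radii[1:])):
            raise ValueError("radii must be strictly increasing")
        if not (0.0 < self.ratio <= 1.0):
            raise ValueError("ratio must be in (0, 1]")

    def to_dict(self) -> dict:
        return {"depth": self.depth, "radii": list(self.radii),
                "ratio": self.ratio, "k_unpool": self.k_unpool,
                "convs_per_layer": self.convs_per_layer, "hidden": self.hidden}

    @classmethod
    def from_dict(cls, d: dict) -> "LayerConfig":
        d = dict(d)
        d["radii"] = tuple(d["radii"])
        return cls(**d)


# ---------------------------------------------------------------------------
# sampling / graph construction (pure geometry, not learned)


def farthest_point_sample(V: np.ndarray, ratio: float,
                          seed: int | None = None,
                          start: int | None = None) -> np.ndarray:
    """Greedy farthest-point sampling of ``ceil(ratio * N)`` indices.

    Each successive index maximizes the minimum distance to the selected
    set; distance ties break to the lowest index.  The start vertex is, in
    order of precedence: ``start`` if given, a seeded-random index if
    ``seed`` is given, else the geometry-canonical vertex farthest from the
    point-cloud centroid (which makes the selection invariant to both vertex
    permutation and rigid motion on generic clouds).
    """
    V = np.asarray(V, dtype=float)
    n = len(V)
    if n == 0:
        raise ValueError("empty point set")
    if not (0.0 < ratio <= 1.0):
        raise ValueError("ratio must be in (0, 1]")
    m = int(np.ceil(ratio * n))
    if start is None:
        if seed is not None:
            start = int(np.random.default_rng(seed).integers(n))
        else:
            start = int(np.argmax(np.linalg.norm(V - V.mean(axis=0), axis=1)))
    selected = np.empty(m, dtype=int)
    selected[0] = start
    mind = np.linalg.norm(V - V[start], axis=1)
    for t in range(1, m):
        nxt = int(np.argmax(mind))  # argmax returns the lowest tied index
        selected[t] = nxt
        mind = np.minimum(mind, np.linalg.norm(V - V[nxt], axis=1))
    return selected


def build_radial_graph(V: np.ndarray, centroids: np.ndarray,
                       radius: float) -> np.ndarray:
    """Directed edges (source vertex j -> centroid position i) for all
    ``j != centroids[i]`` with ``||V_j - V_centroid|| <= radius``.

    Returns (E, 2) int rows ``(j, i)`` with ``i`` indexing into
    ``centroids``; rows are sorted by centroid.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(V)
    src: list[np.ndarray] = []
    dst: list[np.ndarray] = []
    hits = tree.query_ball_point(V[centroids], r=radius)
    for i, idx in enumerate(hits):
        idx = np.array([j for j in idx if j != centroids[i]], dtype=int)
        src.append(idx)
        dst.append(np.full(len(idx), i, dtype=int))
    if not src:
        return np.zeros((0, 2), dtype=int)
    edges = np.column_stack([np.concatenate(src), np.concatenate(dst)])
    return edges[np.argsort(edges[:, 1], kind="stable")]


def knn_interpolation_matrix(coarse_V: np.ndarray, fine_V: np.ndarray,
                             k: int = 3) -> sparse.csr_matrix:
    """Sparse (n_fine, n_coarse) inverse-distance weights over the k nearest
    coarse points; a fine point coincident with a coarse point (d < 1e-8)
    copies it exactly."""
    k = min(k, len(coarse_V))
    tree = cKDTree(coarse_V)
    d, idx = tree.query(fine_V, k=k)
    d = np.atleast_2d(d.reshape(len(fine_V), k))
    idx = idx.reshape(len(fine_V), k)
    w = np.empty_like(d)
    coincident = d[:, 0] < 1e-8
    with np.errstate(divide="ignore"):
        w = 1.0 / np.maximum(d, 1e-12)
    w[coincident] = 0.0
    w[coincident, 0] = 1.0
    w /= w.sum(axis=1, keepdims=True)
    rows = np.repeat(np.arange(len(fine_V)), k)
    return sparse.csr_matrix(
        (w.ravel(), (rows, idx.ravel())), shape=(len(fine_V), len(coarse_V))
    )


def knn_unpool(coarse_V: np.ndarray, coarse_feats: np.ndarray,
               fine_V: np.ndarray, k: int = 3) -> np.ndarray:
    """Distance-weighted mean of the k nearest centroid features."""
    S = knn_interpolation_matrix(coarse_V, fine_V, k)
    return S @ np.asarray(coarse_feats, dtype=float)


# ---------------------------------------------------------------------------
# learned modules


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-lim, lim, size=(n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class CGConv:
    """Crystal-graph convolution with min/max/mean/stdev message pooling.

    For each directed edge j -> i the message is
    ``m_ij = sigmoid(z W_f + b_f) * softplus(z W_s + b_s)`` with
    ``z = [x_i, x_j, e_ij]``; pooled statistics of the incoming messages are
    combined with learned scalar weights and added to the residual ``x_i``.
    Centroids with no neighbors pass through unchanged.
    """

    def __init__(self, hidden: int, n_edge: int, rng: np.random.Generator):
        self.gate = Linear(2 * hidden + n_edge, hidden, rng)
        self.filt = Linear(2 * hidden + n_edge, hidden, rng)
        # weights for (min, max, mean, stdev); start with mean pooling
        self.agg_w = Tensor(np.array([[0.0], [0.0], [1.0], [0.0]]),
                            requires_grad=True)

    def __call__(self, x_centroid: Tensor, x_source: Tensor,
                 edges: np.ndarray, edge_feats: np.ndarray,
                 n_centroids: int,
                 dst_plan: ag.ScatterIndex | None = None,
                 src_plan: ag.ScatterIndex | None = None) -> Tensor:
        if len(edges) == 0:
            return x_centroid
        src, dst = edges[:, 0], edges[:, 1]
        if dst_plan is None:
            dst_plan = ag.ScatterIndex(dst, n_centroids)
        if src_plan is None:
            src_plan = ag.ScatterIndex(src, x_source.data.shape[0])
        z = ag.concat(
            [ag.gather(x_centroid, dst, dst_plan),
             ag.gather(x_source, src, src_plan),
             Tensor(edge_feats)], axis=1
        )
        m = ag.sigmoid(self.gate(z)) * ag.softplus(self.filt(z))
        mn = ag.segment_min(m, dst_plan)
        mx = ag.segment_max(m, dst_plan)
        me = ag.segment_mean(m, dst_plan)
        m2 = ag.segment_mean(m * m, dst_plan)
        sd = ag.sqrt(ag.relu(m2 - me * me) + 1e-12)
        pooled = (self.agg_w.slice_rows(0, 1) * mn
                  + self.agg_w.slice_rows(1, 2) * mx
                  + self.agg_w.slice_rows(2, 3) * me
                  + self.agg_w.slice_rows(3, 4) * sd)
        # exact residual passthrough for centroids with no neighbors
        nonempty = (dst_plan.counts > 0).astype(float)[:, None]
        return x_centroid + pooled * Tensor(nonempty)

    def params(self) -> list[Tensor]:
        return self.gate.params() + self.filt.params() + [self.agg_w]


def global_attention_pool(x: Tensor, f_out: Tensor) -> Tensor:
    """``r = sum_i sigma(f(x_i)) x_i`` — permutation invariant."""
    return (ag.sigmoid(f_out) * x).sum(axis=0, keepdims=True)


def softmax_rows(logits: Tensor) -> Tensor:
    shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    e = ag.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# precomputed multiscale graph structure


@dataclass
class _Level:
    centroids: np.ndarray     # indices into the parent level's vertex set
    edges: np.ndarray         # (E, 2): (source in parent level, centroid pos)
    edge_feats: np.ndarray    # (E, 4) normalized invariant features
    dst_plan: "ag.ScatterIndex | None" = None
    src_plan: "ag.ScatterIndex | None" = None


@dataclass
class GraphHierarchy:
    """Geometry-derived structure shared by every forward pass on a mesh.

    Built once per mesh: FPS centroid sets, radial graphs with normalized
    edge features, and the unpooling interpolation matrices.  Contains no
    learned state, so models of any parameterization can reuse it.
    """

    n_vertices: int
    levels: list[_Level]
    unpool: list[sparse.csr_matrix]   # coarse level l+1 -> level l
    positions: list[np.ndarray] = field(default_factory=list)


def _normalize_edge_feats(ef, radius: float) -> np.ndarray:
    return np.column_stack([
        ef.length / radius,
        ef.angle_source / 180.0,
        ef.angle_target / 180.0,
        ef.angle_normals / 180.0,
    ])


def build_hierarchy(mesh: SurfaceMesh, config: LayerConfig) -> GraphHierarchy:
    if mesh.normals is None:
        raise ValueError("mesh needs normals")
    V = mesh.V
    normals = mesh.normals
    levels: list[_Level] = []
    unpool: list[sparse.csr_matrix] = []
    positions = [V]
    for lvl in range(config.depth):
        centroids = farthest_point_sample(V, config.ratio)
        edges = build_radial_graph(V, centroids, config.radii[lvl])
        if len(edges):
            pair = np.column_stack([edges[:, 0], centroids[edges[:, 1]]])
            ef = _normalize_edge_feats(
                edge_geometry(V, normals, pair), config.radii[lvl]
            )
        else:
            ef = np.zeros((0, 4))
        dst_plan = ag.ScatterIndex(edges[:, 1], len(centroids)) if len(edges) else None
        src_plan = ag.ScatterIndex(edges[:, 0], len(V)) if len(edges) else None
        levels.append(_Level(centroids, edges, ef, dst_plan, src_plan))
        Vc = V[centroids]
        unpool.append(knn_interpolation_matrix(Vc, V, config.k_unpool))
        V, normals = Vc, normals[centroids]
        positions.append(V)
    return GraphHierarchy(mesh.n_vertices, levels, unpool, positions)


# ---------------------------------------------------------------------------
# networks


class _EncoderBase:
    """Shared encoder: input MLP + d levels of (FPS, radial graph, 2 CG convs)."""

    def __init__(self, n_features: int, config: LayerConfig, seed: int):
        self.config = config
        self.n_features = n_features
        rng = np.random.default_rng(seed)
        h = config.hidden
        self.lin_in = Linear(n_features, h, rng)
        self.convs: list[list[CGConv]] = [
            [CGConv(h, 4, rng) for _ in range(config.convs_per_layer)]
            for _ in range(config.depth)
        ]
        self._rng = rng

    def _encode(self, hier: GraphHierarchy, X: np.ndarray):
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature matrix has {X.shape[1]} columns; model expects "
                f"{self.n_features}"
            )
        x = ag.relu(self.lin_in(Tensor(X)))
        skips = [x]
        conv_acts: list[Tensor] = []
        for lvl, level in enumerate(hier.levels):
            xc = ag.gather(x, level.centroids)
            for conv in self.convs[lvl]:
                xc = conv(xc, x, level.edges, level.edge_feats,
                          len(level.centroids), level.dst_plan, level.src_plan)
            x = xc
            skips.append(x)
            conv_acts.append(x)
        return x, skips, conv_acts

    def encoder_params(self) -> list[Tensor]:
        out = self.lin_in.params()
        for lvl in self.convs:
            for c in lvl:
                out += c.params()
        return out


class SegmentationNet(_EncoderBase):
    """Graph U-Net producing per-vertex binding-site probabilities."""

    def __init__(self, n_features: int, config: LayerConfig | None = None,
                 seed: int = 0):
        config = config or LayerConfig()
        super().__init__(n_features, config, seed)
        h = config.hidden
        rng = self._rng
        self.dec = [Linear(2 * h, h, rng) for _ in range(config.depth)]
        self.head1 = Linear(h, h, rng)
        self.head2 = Linear(h, 2, rng)

    def forward(self, hier: GraphHierarchy, X: np.ndarray,
                return_cache: bool = False):
        x, skips, conv_acts = self._encode(hier, X)
        y = x
        for lvl in reversed(range(self.config.depth)):
            y = ag.interp(hier.unpool[lvl], y)
            y = ag.relu(self.dec[lvl](ag.concat([y, skips[lvl]], axis=1)))
        probs = softmax_rows(self.head2(ag.relu(self.head1(y))))
        if return_cache:
            return probs, {"conv_acts": conv_acts}
        return probs

    def predict(self, hier: GraphHierarchy, X: np.ndarray) -> np.ndarray:
        """Per-vertex probability of the binding class (class 1)."""
        return self.forward(hier, X).data[:, 1]

    def params(self) -> list[Tensor]:
        out = self.encoder_params()
        for lin in self.dec:
            out += lin.params()
        return out + self.head1.params() + self.head2.params()

    kind = "segmentation"


class ClassificationNet(_EncoderBase):
    """Whole-mesh classifier with global attention pooling."""

    def __init__(self, n_features: int, config: LayerConfig | None = None,
                 seed: int = 0):
        config = config or LayerConfig()
        super().__init__(n_features, config, seed)
        h = config.hidden
        rng = self._rng
        self.att1 = Linear(h, h, rng)
        self.att2 = Linear(h, 1, rng)
        self.head1 = Linear(h, h, rng)
        self.head2 = Linear(h, 2, rng)

    def forward(self, hier: GraphHierarchy, X: np.ndarray,
                return_cache: bool = False):
        x, _, conv_acts = self._encode(hier, X)
        gate = self.att2(ag.relu(self.att1(x)))
        r = global_attention_pool(x, gate)
        # fixed 1/n input scaling of the head keeps logits O(1) regardless
        # of how many coarse nodes the attention pool summed over
        r = r * (1.0 / max(x.data.shape[0], 1))
        probs = softmax_rows(self.head2(ag.relu(self.head1(r))))
        if return_cache:
            return probs, {"conv_acts": conv_acts}
        return probs

    def predict(self, hier: GraphHierarchy, X: np.ndarray) -> float:
        """Probability that the mesh belongs to class 1."""
        return float(self.forward(hier, X).data[0, 1])

    def params(self) -> list[Tensor]:
        return (self.encoder_params() + self.att1.params() + self.att2.params()
                + self.head1.params() + self.head2.params())

    kind = "classification"


# ---------------------------------------------------------------------------
# checkpoints


def _named_params(model) -> dict[str, Tensor]:
    out: dict[str, Tensor] = {}
    for i, p in enumerate(model.params()):
        out[f"p{i:03d}"] = p
    return out


def save_checkpoint(model, path: str, extra: dict | None = None) -> None:
    """Serialize named parameter tensors plus a config echo (npz container)."""
    arrays = {k: p.data for k, p in _named_params(model).items()}
    meta = {"kind": model.kind, "n_features": model.n_features,
            "config": model.config.to_dict(), "extra": extra or {}}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str):
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        cls = (SegmentationNet if meta["kind"] == "segmentation"
               else ClassificationNet)
        model = cls(meta["n_features"], LayerConfig.from_dict(meta["config"]))
        for k, p in _named_params(model).items():
            p.data = z[k].copy()
    return model, meta.get("extra", {})
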