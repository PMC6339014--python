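"""Regression random forest with ridge leaf models.

The forest learns the patch-wise mapping from low-dose feature vectors to
high-dose detail vectors. Each binary tree partitions feature space with
thresholded split responses; each leaf stores a ridge-regularized linear
model over basis-expanded features, fitted in closed form:

    W^T = (Psi^T Psi + eta I)^{-1} Psi^T X_H

The node impurity combines the label-space residual with a data-space
scatter term weighted by ``k``:

    E(X_L, X_H) = mean_n( ||x_H^n - m(x_L^n)||^2 + k ||x_L^n - mean(x_L)||^2 )

and a candidate split's quality is the size-weighted sum of child
impurities, Q = |Left| E_Left + |Right| E_Right, minimized over a random
candidate pool. During the split search the label term uses the cheap
node-mean predictor (the ridge refit happens once per accepted child);
an exact per-candidate refit is available behind ``exact_split_refit``.

Prediction averages the leaf-model outputs over all trees:

    x_H_hat = (1/T) sum_t W^{l(t)} Psi(x_L)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .patch_sampling import PatchPair, pairs_to_matrices

__all__ = [
    "BasisSpec", "SplitParams", "LeafModel", "TreeNode", "ForestConfig",
    "RegressionForest", "basis_expand", "fit_leaf_model", "split_response",
    "node_purity", "split_quality", "grow_tree", "train_forest",
    "predict_patch", "predict_batch", "save_forest_npz", "load_forest_npz",
    "REJECTED",
]

#: sentinel quality for inadmissible candidate splits (lower Q is better,
#: so an infinite Q can never be selected)
REJECTED = np.inf

_FOREST_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# basis expansion

@dataclass(frozen=True)
class BasisSpec:
    """Feature basis used by the leaf models.

    ``linear`` with a constant gives Psi(x) = [1, x]; ``polynomial`` with
    highest index gamma gives [1, x, x**2, ..., x**gamma] elementwise.
    """

    kind: str = "linear"  # or "polynomial"
    gamma: int = 1
    includes_constant: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "polynomial"):
            raise ValueError(f"unknown basis kind: {self.kind}")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")

    def powers(self) -> list[int]:
        if self.kind == "linear":
            return [1] if self.gamma >= 1 else []
        return list(range(1, self.gamma + 1))

    def expanded_length(self, d: int) -> int:
        return (1 if self.includes_constant else 0) + len(self.powers()) * d


def basis_expand(x_L: np.ndarray, basis: BasisSpec) -> np.ndarray:
    """Expand a feature vector (1-D) or sample matrix (2-D, rows=samples)."""
    x = np.asarray(x_L, dtype=np.float64)
    single = x.ndim == 1
    X = x[None, :] if single else x
    blocks = []
    if basis.includes_constant:
        blocks.append(np.ones((X.shape[0], 1)))
    for p in basis.powers():
        blocks.append(X if p == 1 else X ** p)
    if not blocks:
        raise ValueError("empty basis: no constant and gamma=0")
    out = np.concatenate(blocks, axis=1)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# leaf models

@dataclass
class LeafModel:
    """Ridge-regression leaf: predicts W @ Psi(x_L)."""

    W: np.ndarray  # (D_H, expanded basis length)
    n_train: int

    def predict(self, X_L: np.ndarray, basis: BasisSpec) -> np.ndarray:
        return basis_expand(X_L, basis) @ self.W.T


def fit_leaf_model(X_L: np.ndarray, X_H: np.ndarray, basis: BasisSpec,
                   ridge: float) -> LeafModel:
    """Closed-form regularized least squares for one leaf.

    Solves min_W ||X_H - Psi(X_L) W^T||_F^2 + eta ||W||_F^2 via the normal
    equations; with ridge=0 the Gram matrix must be nonsingular.
    """
    X_L = np.atleast_2d(np.asarray(X_L, dtype=np.float64))
    X_H = np.atleast_2d(np.asarray(X_H, dtype=np.float64))
    if len(X_L) < 1:
        raise ValueError("fit_leaf_model needs at least one sample")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    Psi = basis_expand(X_L, basis)
    G = Psi.T @ Psi + ridge * np.eye(Psi.shape[1])
    try:
        Wt = np.linalg.solve(G, Psi.T @ X_H)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular leaf system: Gram matrix is not invertible with "
            f"ridge={ridge}; use a positive ridge") from exc
    return LeafModel(W=Wt.T, n_train=len(X_L))


# ---------------------------------------------------------------------------
# splits

@dataclass(frozen=True)
class SplitParams:
    """Thresholded split response r(x) = x[i] - threshold, or the pairwise
    form r(x) = x[i] - x[j] - threshold when a second index is given."""

    feature_index: int
    threshold: float
    second_feature_index: int | None = None


def _responses(X_L: np.ndarray, theta: SplitParams) -> np.ndarray:
    d = X_L.shape[1]
    if not 0 <= theta.feature_index < d:
        raise IndexError(f"feature index {theta.feature_index} out of range (d={d})")
    r = X_L[:, theta.feature_index].copy()
    if theta.second_feature_index is not None:
        if not 0 <= theta.second_feature_index < d:
            raise IndexError(f"feature index {theta.second_feature_index} out of range (d={d})")
        r -= X_L[:, theta.second_feature_index]
    return r - theta.threshold


def split_response(x_L: np.ndarray, theta: SplitParams) -> int:
    """Binary routing: 0 if r(x) < 0, else 1 (equality routes right)."""
    r = _responses(np.asarray(x_L, dtype=np.float64)[None, :], theta)[0]
    return 0 if r < 0 else 1


def node_purity(X_L: np.ndarray, X_H: np.ndarray, k: float, basis: BasisSpec,
                ridge: float, model: LeafModel | None = None) -> float:
    """Impurity of one node: mean prediction residual plus k times the
    data-space scatter about the node mean. ``model`` defaults to the
    node's own fitted ridge leaf."""
    X_L = np.atleast_2d(np.asarray(X_L, dtype=np.float64))
    X_H = np.atleast_2d(np.asarray(X_H, dtype=np.float64))
    if len(X_L) == 0:
        raise ValueError("empty node")
    if model is None:
        model = fit_leaf_model(X_L, X_H, basis, ridge)
    resid = X_H - model.predict(X_L, basis)
    label = np.sum(resid ** 2, axis=1).mean()
    scatter = np.sum((X_L - X_L.mean(axis=0)) ** 2, axis=1).mean()
    return float(label + k * scatter)


def _cheap_child_sse(X_L, X_H, k, mask):
    """n_c * E_c with the node-mean predictor, for one child selected by mask."""
    n_c = int(mask.sum())
    if n_c == 0:
        return 0.0
    H = X_H[mask]
    L = X_L[mask]
    sse_h = float(np.sum((H - H.mean(axis=0)) ** 2))
    sse_l = float(np.sum((L - L.mean(axis=0)) ** 2))
    return sse_h + k * sse_l


def split_quality(theta: SplitParams, X_L: np.ndarray, X_H: np.ndarray,
                  k: float, basis: BasisSpec, ridge: float,
                  min_leaf_samples: int = 1,
                  exact_refit: bool = False) -> float:
    """Weighted child impurity Q = |L| E_L + |R| E_R; lower is better.

    Candidates leaving fewer than ``min_leaf_samples`` on a side return
    the :data:`REJECTED` sentinel rather than raising.
    """
    X_L = np.atleast_2d(np.asarray(X_L, dtype=np.float64))
    X_H = np.atleast_2d(np.asarray(X_H, dtype=np.float64))
    right = _responses(X_L, theta) >= 0
    n_r = int(right.sum())
    n_l = len(X_L) - n_r
    if min(n_l, n_r) < min_leaf_samples:
        return REJECTED
    if exact_refit:
        q = 0.0
        for mask in (~right, right):
            q += mask.sum() * node_purity(X_L[mask], X_H[mask], k, basis, ridge)
        return float(q)
    return _cheap_child_sse(X_L, X_H, k, ~right) + _cheap_child_sse(X_L, X_H, k, right)


# ---------------------------------------------------------------------------
# tree structure

@dataclass
class TreeNode:
    depth: int
    split: SplitParams | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    leaf: LeafModel | None = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters. Defaults follow the reference setting
    T=10, max depth 15, ridge eta=0.01, split regularizer k=1."""

    n_trees: int = 10
    max_depth: int = 15
    ridge: float = 0.01
    split_reg: float = 1.0
    n_candidate_splits: int = 40
    min_leaf_samples: int | None = None  # default max(32, basis length + 1)
    bootstrap_fraction: float = 1.0
    split_kind: str = "single"  # or "pair"
    exact_split_refit: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.max_depth < 0:
            raise ValueError("max_depth must be nonnegative")
        if self.ridge <= 0:
            raise ValueError("ridge must be positive")
        if self.split_reg < 0:
            raise ValueError("split_reg must be nonnegative")
        if self.n_candidate_splits < 1:
            raise ValueError("n_candidate_splits must be positive")
        if not 0.0 < self.bootstrap_fraction <= 1.0:
            raise ValueError("bootstrap_fraction must be in (0, 1]")
        if self.split_kind not in ("single", "pair"):
            raise ValueError(f"unknown split kind: {self.split_kind}")

    def resolved_min_leaf(self, basis: BasisSpec, d: int) -> int:
        if self.min_leaf_samples is not None:
            return self.min_leaf_samples
        return max(32, basis.expanded_length(d) + 1)


@dataclass
class RegressionForest:
    trees: list[TreeNode]
    basis: BasisSpec
    config: ForestConfig
    n_features: int
    n_targets: int


# ---------------------------------------------------------------------------
# growing

#: relative improvement a split must achieve over the unsplit node
_MIN_RELATIVE_GAIN = 1e-6


def _draw_candidates(X_L: np.ndarray, rng: np.random.Generator,
                     cfg: ForestConfig) -> list[SplitParams]:
    d = X_L.shape[1]
    cands = []
    for _ in range(cfg.n_candidate_splits):
        i = int(rng.integers(d))
        j = None
        if cfg.split_kind == "pair" and d > 1:
            j = int(rng.integers(d))
            if j == i:
                j = (j + 1) % d
        r = X_L[:, i] if j is None else X_L[:, i] - X_L[:, j]
        lo, hi = np.percentile(r, [5.0, 95.0])
        thr = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        cands.append(SplitParams(i, thr, j))
    return cands


def _score_candidates_cheap(X_L, X_H, sL, sH, cands, k, min_leaf):
    """Vectorized Q for all candidates with the node-mean predictor.

    sL, sH are precomputed per-sample squared norms of X_L, X_H. Uses
    SSE(child) = sum ||v||^2 - ||sum v||^2 / n per child and candidate.
    """
    n = len(X_L)
    R = np.empty((n, len(cands)))
    for c, th in enumerate(cands):
        col = X_L[:, th.feature_index]
        if th.second_feature_index is not None:
            col = col - X_L[:, th.second_feature_index]
        R[:, c] = col - th.threshold
    right = (R >= 0.0).astype(np.float64)

    n_r = right.sum(axis=0)
    n_l = n - n_r
    tot_h = X_H.sum(axis=0)
    tot_l = X_L.sum(axis=0)
    tot_sh = sH.sum()
    tot_sl = sL.sum()

    sum_h_r = right.T @ X_H          # (C, D_H)
    sum_l_r = right.T @ X_L          # (C, D_L)
    s_h_r = right.T @ sH
    s_l_r = right.T @ sL

    with np.errstate(divide="ignore", invalid="ignore"):
        def sse(s_tot, vec_sum, count):
            out = s_tot - np.sum(vec_sum ** 2, axis=1) / count
            return np.where(count > 0, out, 0.0)

        q = (sse(s_h_r, sum_h_r, n_r)
             + sse(tot_sh - s_h_r, tot_h - sum_h_r, n_l))
        q_l = (sse(s_l_r, sum_l_r, n_r)
               + sse(tot_sl - s_l_r, tot_l - sum_l_r, n_l))
    q = q + k * q_l
    q = np.maximum(q, 0.0)  # guard tiny negative round-off
    q[np.minimum(n_l, n_r) < min_leaf] = REJECTED
    return q


def _grow(X_L, X_H, sL, sH, depth, rng, cfg, basis, min_leaf) -> TreeNode:
    n = len(X_L)
    if depth >= cfg.max_depth or n < 2 * min_leaf:
        return TreeNode(depth=depth, leaf=fit_leaf_model(X_L, X_H, basis, cfg.ridge))

    cands = _draw_candidates(X_L, rng, cfg)
    if cfg.exact_split_refit:
        q = np.array([split_quality(th, X_L, X_H, cfg.split_reg, basis,
                                    cfg.ridge, min_leaf, exact_refit=True)
                      for th in cands])
    else:
        q = _score_candidates_cheap(X_L, X_H, sL, sH, cands, cfg.split_reg,
                                    min_leaf)

    best = int(np.argmin(q))  # ties -> lowest candidate index
    parent_sse = _cheap_child_sse(X_L, X_H, cfg.split_reg,
                                  np.ones(n, dtype=bool))
    if not np.isfinite(q[best]) or q[best] >= parent_sse * (1.0 - _MIN_RELATIVE_GAIN):
        return TreeNode(depth=depth, leaf=fit_leaf_model(X_L, X_H, basis, cfg.ridge))

    theta = cands[best]
    right = _responses(X_L, theta) >= 0
    left = ~right
    return TreeNode(
        depth=depth,
        split=theta,
        left=_grow(X_L[left], X_H[left], sL[left], sH[left], depth + 1,
                   rng, cfg, basis, min_leaf),
        right=_grow(X_L[right], X_H[right], sL[right], sH[right], depth + 1,
                    rng, cfg, basis, min_leaf),
    )


def _as_matrices(samples) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, tuple) and len(samples) == 2:
        return (np.atleast_2d(np.asarray(samples[0], dtype=np.float64)),
                np.atleast_2d(np.asarray(samples[1], dtype=np.float64)))
    return pairs_to_matrices(list(samples))


def grow_tree(samples, cfg: ForestConfig, basis: BasisSpec,
              rng_seed: int) -> TreeNode:
    """Grow one tree by greedy recursive splitting, deterministic in seed.

    ``samples`` is a list of :class:`~rfctsr.patch_sampling.PatchPair` or a
    ``(X_L, X_H)`` matrix pair with rows as samples.
    """
    X_L, X_H = _as_matrices(samples)
    min_leaf = cfg.resolved_min_leaf(basis, X_L.shape[1])
    if len(X_L) < min_leaf:
        raise ValueError(f"need at least {min_leaf} samples at the root, got {len(X_L)}")
    rng = np.random.default_rng(rng_seed)
    sL = np.sum(X_L ** 2, axis=1)
    sH = np.sum(X_H ** 2, axis=1)
    return _grow(X_L, X_H, sL, sH, 0, rng, cfg, basis, min_leaf)


def train_forest(samples, cfg: ForestConfig,
                 basis: BasisSpec = BasisSpec()) -> RegressionForest:
    """Train T trees, each on an independent bootstrap draw (with
    replacement) of ``bootstrap_fraction * N`` samples."""
    X_L, X_H = _as_matrices(samples)
    n = len(X_L)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2 * cfg.n_trees)
    n_draw = max(1, int(round(cfg.bootstrap_fraction * n)))
    trees = []
    for t in range(cfg.n_trees):
        boot_rng = np.random.default_rng(int(seeds[2 * t] % (2 ** 31)))
        idx = boot_rng.integers(n, size=n_draw)
        trees.append(grow_tree((X_L[idx], X_H[idx]), cfg, basis,
                               int(seeds[2 * t + 1] % (2 ** 31))))
    return RegressionForest(trees=trees, basis=basis, config=cfg,
                            n_features=X_L.shape[1], n_targets=X_H.shape[1])


# ---------------------------------------------------------------------------
# prediction

def _tree_predict(node: TreeNode, X_L: np.ndarray, Psi: np.ndarray,
                  idx: np.ndarray, out: np.ndarray) -> None:
    if node.is_leaf:
        out[idx] += Psi[idx] @ node.leaf.W.T
        return
    right = _responses(X_L[idx], node.split) >= 0
    _tree_predict(node.left, X_L, Psi, idx[~right], out)
    _tree_predict(node.right, X_L, Psi, idx[right], out)


def predict_batch(forest: RegressionForest, X_L: np.ndarray) -> np.ndarray:
    """Forest prediction for a sample matrix (rows = feature vectors)."""
    X_L = np.atleast_2d(np.asarray(X_L, dtype=np.float64))
    if X_L.shape[1] != forest.n_features:
        raise ValueError(f"feature dimension {X_L.shape[1]} != trained {forest.n_features}")
    Psi = basis_expand(X_L, forest.basis)
    out = np.zeros((len(X_L), forest.n_targets))
    idx = np.arange(len(X_L))
    for tree in forest.trees:
        _tree_predict(tree, X_L, Psi, idx, out)
    return out / len(forest.trees)


def predict_patch(forest: RegressionForest, x_L: np.ndarray) -> np.ndarray:
    """Predicted HD detail vector for a single LD feature vector."""
    return predict_batch(forest, np.asarray(x_L)[None, :])[0]


# ---------------------------------------------------------------------------
# serialization (topology as flat records + one stacked W array)

def _flatten(node: TreeNode, nodes: list, Ws: list) -> int:
    my = len(nodes)
    nodes.append(None)  # placeholder
    if node.is_leaf:
        Ws.append(node.leaf.W)
        nodes[my] = dict(is_leaf=1, depth=node.depth, w_idx=len(Ws) - 1,
                         n_train=node.leaf.n_train, feature=-1, feature2=-1,
                         threshold=0.0, left=-1, right=-1)
    else:
        left = _flatten(node.left, nodes, Ws)
        right = _flatten(node.right, nodes, Ws)
        f2 = node.split.second_feature_index
        nodes[my] = dict(is_leaf=0, depth=node.depth, w_idx=-1, n_train=-1,
                         feature=node.split.feature_index,
                         feature2=-1 if f2 is None else f2,
                         threshold=node.split.threshold, left=left, right=right)
    return my


def _unflatten(records, Ws, i: int) -> TreeNode:
    rec = records[i]
    if rec["is_leaf"]:
        return TreeNode(depth=int(rec["depth"]),
                        leaf=LeafModel(W=Ws[int(rec["w_idx"])],
                                       n_train=int(rec["n_train"])))
    f2 = int(rec["feature2"])
    return TreeNode(
        depth=int(rec["depth"]),
        split=SplitParams(int(rec["feature"]), float(rec["threshold"]),
                          None if f2 < 0 else f2),
        left=_unflatten(records, Ws, int(rec["left"])),
        right=_unflatten(records, Ws, int(rec["right"])),
    )


_INT_FIELDS = ("is_leaf", "depth", "w_idx", "n_train", "feature", "feature2",
               "left", "right")


def forest_to_arrays(forest: RegressionForest) -> dict[str, np.ndarray | str]:
    """Serialize to a dict of arrays plus a JSON metadata string."""
    Ws: list[np.ndarray] = []
    all_records = []
    tree_offsets = []
    for tree in forest.trees:
        nodes: list = []
        _flatten(tree, nodes, Ws)
        tree_offsets.append(len(all_records))
        all_records.extend(nodes)

    out: dict[str, np.ndarray | str] = {}
    for f in _INT_FIELDS:
        out[f"node_{f}"] = np.array([r[f] for r in all_records], dtype=np.int64)
    out["node_threshold"] = np.array([r["threshold"] for r in all_records])
    out["tree_offsets"] = np.array(tree_offsets, dtype=np.int64)
    out["W_stack"] = np.stack(Ws) if Ws else np.zeros((0, 0, 0))
    meta = dict(format_version=_FOREST_FORMAT_VERSION,
                basis=asdict(forest.basis), config=asdict(forest.config),
                n_features=forest.n_features, n_targets=forest.n_targets)
    out["meta_json"] = json.dumps(meta)
    return out


def forest_from_arrays(data) -> RegressionForest:
    meta = json.loads(str(data["meta_json"]))
    if meta["format_version"] != _FOREST_FORMAT_VERSION:
        raise ValueError(f"unsupported forest format version {meta['format_version']}")
    n_nodes = len(data["node_is_leaf"])
    records = [{f: data[f"node_{f}"][i] for f in _INT_FIELDS}
               | {"threshold": data["node_threshold"][i]}
               for i in range(n_nodes)]
    Ws = [np.asarray(w) for w in data["W_stack"]]
    offsets = [int(o) for o in data["tree_offsets"]] + [n_nodes]
    # child indices are local to each tree's record block
    trees = [_unflatten(records[offsets[t]:offsets[t + 1]], Ws, 0)
             for t in range(len(offsets) - 1)]
    return RegressionForest(trees=trees, basis=BasisSpec(**meta["basis"]),
                            config=ForestConfig(**meta["config"]),
                            n_features=meta["n_features"],
                            n_targets=meta["n_targets"])


def save_forest_npz(forest: RegressionForest, path) -> None:
    np.savez_compressed(path, **forest_to_arrays(forest))


def load_forest_npz(path) -> RegressionForest:
    with np.load(path, allow_pickle=False) as data:
        return forest_from_arrays({k: data[k] for k in data.files})
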