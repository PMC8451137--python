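"""Leaf-wise gradient-boosted regression trees with split-gain accounting.

The booster fits an additive ensemble of regression trees to first- and
second-order gradients of the objective. Each tree is grown *leaf-wise*:
at every step the best candidate split of every current leaf is known, and
only the single leaf whose best split has the globally highest gain is
split, so trees are asymmetric and concentrate depth where it pays.

Split quality uses the canonical second-order formula with L2
regularisation lambda on leaf weights,

    gain = G_L^2/(H_L+lam) + G_R^2/(H_R+lam) - (G_L+G_R)^2/(H_L+H_R+lam),

where G/H are sums of per-sample gradients/hessians, and the weight of a
leaf is -G/(H+lam) (scaled by the learning rate). The gain accumulated at
every accepted split, summed per feature over all trees, is the
information-gain (IG) feature importance used for marker-panel design.

Genotype codes are treated as ordered integers split by threshold: with at
most ten codes per marker every threshold split realises a contiguous
partition of the genotype classes, which is why retraining after any
strictly monotone per-marker recoding (e.g. additive 0/1/2 versus the
ten-state codes of a biallelic marker) reproduces the same trees and
predictions.

Split search is exact: every distinct observed value of every feature is a
candidate threshold (values <= threshold go left). Missing values are
routed to the child with more (non-missing) training samples. Ties in gain
are broken toward the lowest feature index, then the lowest threshold; ties
in the leaf-selection step go to the oldest leaf — all choices are
deterministic so training is bit-reproducible.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["BoostedModel", "FeatureImportance", "TreeNode", "fit", "predict",
           "feature_importance", "grid_search"]


@dataclass
class TreeNode:
    node_id: int
    n_samples: int
    feature: int | None = None
    threshold: float | None = None
    gain: float | None = None
    left: int | None = None
    right: int | None = None
    missing_direction: str = "left"
    leaf_value: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class Tree:
    nodes: list[TreeNode]
    class_index: int = 0  # which class this tree updates (multiclass)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Sum of leaf values reached by each row of X."""
        out = np.zeros(X.shape[0])
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            nid, idx = stack.pop()
            node = self.nodes[nid]
            if node.is_leaf:
                out[idx] = node.leaf_value
                continue
            col = X[idx, node.feature]
            miss = np.isnan(col)
            goleft = np.where(miss, node.missing_direction == "left",
                              col <= node.threshold)
            stack.append((node.left, idx[goleft]))
            stack.append((node.right, idx[~goleft]))
        return out


@dataclass
class BoostedModel:
    objective: str                      # "l2" | "binary" | "multiclass:K"
    base_score: np.ndarray              # scalar array, or K scores
    trees: list[Tree]
    learning_rate: float
    max_leaves: int
    min_samples_leaf: int
    lambda_l2: float
    n_iterations: int
    n_features: int
    feature_gain: np.ndarray
    feature_split_count: np.ndarray
    marker_ids: list[str] | None = None
    scheme: str | None = None
    classes_: list | None = None

    @property
    def n_classes(self) -> int:
        if self.objective.startswith("multiclass:"):
            return int(self.objective.split(":")[1])
        return 1

    def to_json(self) -> str:
        d = {
            "objective": self.objective,
            "base_score": np.asarray(self.base_score).tolist(),
            "learning_rate": self.learning_rate,
            "max_leaves": self.max_leaves,
            "min_samples_leaf": self.min_samples_leaf,
            "lambda_l2": self.lambda_l2,
            "n_iterations": self.n_iterations,
            "n_features": self.n_features,
            "feature_gain": self.feature_gain.tolist(),
            "feature_split_count": self.feature_split_count.tolist(),
            "marker_ids": self.marker_ids,
            "scheme": self.scheme,
            "classes": self.classes_,
            "trees": [
                {"class_index": t.class_index,
                 "nodes": [asdict(n) for n in t.nodes]}
                for t in self.trees
            ],
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "BoostedModel":
        d = json.loads(s)
        trees = [
            Tree([TreeNode(**n) for n in t["nodes"]], t["class_index"])
            for t in d["trees"]
        ]
        return cls(
            d["objective"], np.asarray(d["base_score"], dtype=float), trees,
            d["learning_rate"], d["max_leaves"], d["min_samples_leaf"],
            d["lambda_l2"], d["n_iterations"], d["n_features"],
            np.asarray(d["feature_gain"]), np.asarray(d["feature_split_count"]),
            d["marker_ids"], d["scheme"], d["classes"],
        )


@dataclass
class FeatureImportance:
    marker_ids: list[str]
    total_gain: np.ndarray
    split_count: np.ndarray

    def top(self, k: int) -> list[int]:
        """Indices of the k highest-gain markers (stable order on ties)."""
        order = np.lexsort((np.arange(len(self.total_gain)),
                            -self.total_gain))
        return order[:k].tolist()


# ---------------------------------------------------------------------------
# Split search machinery


class _BinnedData:
    """Per-feature value bins shared by every tree of a booster.

    Bin 0 of each feature holds missing values; bins 1..k hold the sorted
    distinct observed values. Thresholds are the distinct values themselves
    (all but the last), so split search over bins is *exact*.
    """

    def __init__(self, X: np.ndarray):
        n, F = X.shape
        self.n, self.F = n, F
        offsets = np.zeros(F + 1, dtype=np.int64)
        codes = np.zeros((n, F), dtype=np.int64)
        bin_values: list[np.ndarray] = []
        for f in range(F):
            col = X[:, f]
            miss = np.isnan(col)
            vals = np.unique(col[~miss])
            bin_values.append(vals)
            c = np.zeros(n, dtype=np.int64)
            c[~miss] = np.searchsorted(vals, col[~miss]) + 1
            codes[:, f] = c + offsets[f]
            offsets[f + 1] = offsets[f] + len(vals) + 1
        self.codes = codes                  # global bin index per cell
        self.total_bins = int(offsets[-1])
        self.offsets = offsets

        # Candidate-threshold index arrays, ordered by (feature, threshold):
        cand_pos, cand_feat, cand_thresh, cand_off, cand_last = [], [], [], [], []
        for f in range(F):
            vals = bin_values[f]
            off = offsets[f]
            for b in range(1, len(vals)):       # left prefix ends at bin b
                cand_pos.append(off + b)
                cand_feat.append(f)
                cand_thresh.append(vals[b - 1])
                cand_off.append(off)
                cand_last.append(off + len(vals))
        self.cand_pos = np.asarray(cand_pos, dtype=np.int64)
        self.cand_feat = np.asarray(cand_feat, dtype=np.int64)
        self.cand_thresh = np.asarray(cand_thresh, dtype=np.float64)
        self.cand_off = np.asarray(cand_off, dtype=np.int64)
        self.cand_last = np.asarray(cand_last, dtype=np.int64)

    def hist(self, idx: np.ndarray, g: np.ndarray, h: np.ndarray):
        """Gradient/hessian/count histograms over the global bin space."""
        flat = self.codes[idx].ravel()
        F = self.F
        G = np.bincount(flat, weights=np.repeat(g[idx], F),
                        minlength=self.total_bins)
        H = np.bincount(flat, weights=np.repeat(h[idx], F),
                        minlength=self.total_bins)
        C = np.bincount(flat, minlength=self.total_bins).astype(np.float64)
        # every row lands once per feature, so counts are per-feature exact
        return G, H, C


def _best_split(data: _BinnedData, G, H, C, lam: float, msl: int):
    """Best (gain, cand_index, missing_left) over all features/thresholds.

    Candidates are ordered by (feature, threshold); the first argmax
    realises the tie rule. Returns gain=-inf when no valid split exists.
    """
    if len(data.cand_pos) == 0:
        return -np.inf, -1, True
    csG, csH, csC = np.cumsum(G), np.cumsum(H), np.cumsum(C)
    GL0 = csG[data.cand_pos] - csG[data.cand_off]
    HL0 = csH[data.cand_pos] - csH[data.cand_off]
    CL0 = csC[data.cand_pos] - csC[data.cand_off]
    Gnm = csG[data.cand_last] - csG[data.cand_off]
    Hnm = csH[data.cand_last] - csH[data.cand_off]
    Cnm = csC[data.cand_last] - csC[data.cand_off]
    GR0, HR0, CR0 = Gnm - GL0, Hnm - HL0, Cnm - CL0
    Gm, Hm, Cm = G[data.cand_off], H[data.cand_off], C[data.cand_off]
    missing_left = CL0 >= CR0          # more-populated child gets missing
    GL = GL0 + np.where(missing_left, Gm, 0.0)
    HL = HL0 + np.where(missing_left, Hm, 0.0)
    CL = CL0 + np.where(missing_left, Cm, 0.0)
    GR = GR0 + np.where(missing_left, 0.0, Gm)
    HR = HR0 + np.where(missing_left, 0.0, Hm)
    CR = CR0 + np.where(missing_left, 0.0, Cm)
    Gp, Hp = GL + GR, HL + HR
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = GL * GL / (HL + lam) + GR * GR / (HR + lam) \
            - Gp * Gp / (Hp + lam)
    gain = np.nan_to_num(gain, nan=-np.inf)
    valid = (CL >= max(msl, 1)) & (CR >= max(msl, 1)) & (CL0 > 0) & (CR0 > 0)
    gain = np.where(valid, gain, -np.inf)
    best = int(np.argmax(gain))
    return float(gain[best]), best, bool(missing_left[best])


class _Leaf:
    __slots__ = ("node_id", "idx", "hist", "best_gain", "best_cand",
                 "best_missing_left", "order")

    def __init__(self, node_id, idx, hist, best, order):
        self.node_id = node_id
        self.idx = idx
        self.hist = hist
        self.best_gain, self.best_cand, self.best_missing_left = best
        self.order = order


def _grow_tree(data: _BinnedData, X: np.ndarray, g: np.ndarray,
               h: np.ndarray, params: dict, feature_gain: np.ndarray,
               feature_split_count: np.ndarray,
               class_index: int = 0) -> Tree:
    lam = params["lambda_l2"]
    msl = params["min_samples_leaf"]
    max_leaves = params["max_leaves"]
    lr = params["learning_rate"]

    nodes = [TreeNode(0, data.n)]
    root_idx = np.arange(data.n)
    root_hist = data.hist(root_idx, g, h)
    leaves = [_Leaf(0, root_idx, root_hist,
                    _best_split(data, *root_hist, lam, msl), 0)]
    order_counter = 1

    while len(leaves) < max_leaves:
        # globally best leaf; strict > keeps the oldest leaf on ties
        best_leaf = None
        for leaf in sorted(leaves, key=lambda l: l.order):
            if leaf.best_gain > 0 and (best_leaf is None
                                       or leaf.best_gain > best_leaf.best_gain):
                best_leaf = leaf
        if best_leaf is None:
            break

        c = best_leaf.best_cand
        f = int(data.cand_feat[c])
        thr = float(data.cand_thresh[c])
        miss_left = best_leaf.best_missing_left

        col = X[best_leaf.idx, f]
        miss = np.isnan(col)
        goleft = np.where(miss, miss_left, col <= thr)
        left_idx = best_leaf.idx[goleft]
        right_idx = best_leaf.idx[~goleft]

        node = nodes[best_leaf.node_id]
        node.feature = f
        node.threshold = thr
        node.gain = best_leaf.best_gain
        node.missing_direction = "left" if miss_left else "right"
        node.left = len(nodes)
        node.right = len(nodes) + 1
        nodes.append(TreeNode(node.left, len(left_idx)))
        nodes.append(TreeNode(node.right, len(right_idx)))
        feature_gain[f] += best_leaf.best_gain
        feature_split_count[f] += 1

        # histogram subtraction: compute the smaller child, derive the other
        if len(left_idx) <= len(right_idx):
            small_idx, big_idx = left_idx, right_idx
        else:
            small_idx, big_idx = right_idx, left_idx
        small_hist = data.hist(small_idx, g, h)
        big_hist = tuple(p - s for p, s in zip(best_leaf.hist, small_hist))
        if len(left_idx) <= len(right_idx):
            lhist, rhist = small_hist, big_hist
        else:
            lhist, rhist = big_hist, small_hist

        leaves.remove(best_leaf)
        leaves.append(_Leaf(node.left, left_idx, lhist,
                            _best_split(data, *lhist, lam, msl),
                            order_counter))
        leaves.append(_Leaf(node.right, right_idx, rhist,
                            _best_split(data, *rhist, lam, msl),
                            order_counter + 1))
        order_counter += 2

    for leaf in leaves:
        G = g[leaf.idx].sum()
        H = h[leaf.idx].sum()
        nodes[leaf.node_id].leaf_value = float(-G / (H + lam) * lr)
    return Tree(nodes, class_index)


# ---------------------------------------------------------------------------
# Objectives


def _softmax(raw: np.ndarray) -> np.ndarray:
    z = raw - raw.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _resolve_X(X) -> tuple[np.ndarray, list[str] | None, str | None]:
    """Accept an EncodedMatrix or a plain numeric array (NaN = missing)."""
    from .geno import EncodedMatrix
    if isinstance(X, EncodedMatrix):
        return X.to_array(), list(X.marker_ids), X.scheme
    return np.asarray(X, dtype=np.float64), None, None


DEFAULT_PARAMS = {
    "learning_rate": 0.1,
    "n_iterations": 100,
    "max_leaves": 31,
    "min_samples_leaf": 20,
    "lambda_l2": 1.0,
}


def fit(X, y, objective: str = "l2", **params) -> BoostedModel:
    """Train a boosted ensemble.

    Parameters
    ----------
    X : EncodedMatrix or (n, p) array
        Numeric features; NaN (or the encoded missing sentinel) is missing.
    y : array
        Targets: reals for "l2", 0/1 for "binary", integer or string class
        labels for "multiclass" (K inferred, or pass "multiclass:K").
    objective : str
        "l2", "binary", or "multiclass[:K]".
    **params
        learning_rate, n_iterations, max_leaves, min_samples_leaf,
        lambda_l2 (see DEFAULT_PARAMS).
    """
    p = dict(DEFAULT_PARAMS)
    unknown = set(params) - set(p)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    p.update(params)
    if p["max_leaves"] < 2:
        raise ValueError("max_leaves must be >= 2")

    Xa, marker_ids, scheme = _resolve_X(X)
    y = np.asarray(y)
    n, F = Xa.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")

    classes = None
    if objective == "l2":
        yt = y.astype(float)
        if not np.isfinite(yt).all():
            raise ValueError("non-finite targets")
        base = np.array([yt.mean()])
    elif objective == "binary":
        yt = y.astype(float)
        if not np.isfinite(yt).all():
            raise ValueError("non-finite targets")
        if not set(np.unique(yt)) <= {0.0, 1.0}:
            raise ValueError("binary objective needs 0/1 targets")
        pbar = np.clip(yt.mean(), 1e-12, 1 - 1e-12)
        base = np.array([np.log(pbar / (1 - pbar))])
    elif objective.startswith("multiclass"):
        uniq = sorted(set(np.asarray(y).tolist()))
        classes = uniq
        K = int(objective.split(":")[1]) if ":" in objective else len(uniq)
        if len(uniq) > K:
            raise ValueError("more classes observed than declared")
        objective = f"multiclass:{K}"
        ycode = np.array([uniq.index(v) for v in np.asarray(y).tolist()])
        onehot = np.eye(K)[ycode]
        freq = np.clip(onehot.mean(axis=0), 1e-12, 1.0)
        base = np.log(freq)
        yt = ycode
    else:
        raise ValueError(f"unknown objective {objective!r}")

    data = _BinnedData(Xa)
    feature_gain = np.zeros(F)
    feature_split_count = np.zeros(F, dtype=np.int64)
    trees: list[Tree] = []

    if objective in ("l2", "binary"):
        raw = np.full(n, base[0])
        for _ in range(p["n_iterations"]):
            if objective == "l2":
                g = raw - yt
                h = np.ones(n)
            else:
                prob = _sigmoid(raw)
                g = prob - yt
                h = prob * (1 - prob)
            tree = _grow_tree(data, Xa, g, h, p, feature_gain,
                              feature_split_count)
            trees.append(tree)
            raw += tree.predict(Xa)
    else:
        K = int(objective.split(":")[1])
        raw = np.tile(base, (n, 1))
        for _ in range(p["n_iterations"]):
            prob = _softmax(raw)
            for k in range(K):
                g = prob[:, k] - (yt == k)
                h = prob[:, k] * (1 - prob[:, k])
                tree = _grow_tree(data, Xa, g, h, p, feature_gain,
                                  feature_split_count, class_index=k)
                trees.append(tree)
                raw[:, k] += tree.predict(Xa)

    return BoostedModel(
        objective=objective, base_score=base, trees=trees,
        learning_rate=p["learning_rate"], max_leaves=p["max_leaves"],
        min_samples_leaf=p["min_samples_leaf"], lambda_l2=p["lambda_l2"],
        n_iterations=p["n_iterations"], n_features=F,
        feature_gain=feature_gain, feature_split_count=feature_split_count,
        marker_ids=marker_ids, scheme=scheme, classes_=classes,
    )


def predict(model: BoostedModel, X, raw: bool = False) -> np.ndarray:
    """Sum base score and all tree outputs; transform per objective.

    Regression returns reals; "binary" returns P(class 1); multiclass
    returns an (n, K) matrix of softmax probabilities.
    """
    Xa, marker_ids, scheme = _resolve_X(X)
    if Xa.shape[1] != model.n_features:
        raise ValueError(
            f"feature count mismatch: model has {model.n_features}, "
            f"X has {Xa.shape[1]}")
    if model.marker_ids is not None and marker_ids is not None \
            and marker_ids != model.marker_ids:
        raise ValueError("marker ids/order differ from training")
    if model.scheme is not None and scheme is not None \
            and scheme != model.scheme:
        raise ValueError(
            f"encoding scheme mismatch: model {model.scheme}, X {scheme}")
    n = Xa.shape[0]
    if model.n_classes == 1:
        out = np.full(n, model.base_score[0])
        for tree in model.trees:
            out += tree.predict(Xa)
        if raw or model.objective == "l2":
            return out
        return _sigmoid(out)
    K = model.n_classes
    out = np.tile(model.base_score, (n, 1))
    for tree in model.trees:
        out[:, tree.class_index] += tree.predict(Xa)
    if raw:
        return out
    return _softmax(out)


def feature_importance(model: BoostedModel) -> FeatureImportance:
    """Cumulative split gain (IG) and split counts per marker."""
    ids = model.marker_ids or [f"f{j}" for j in range(model.n_features)]
    return FeatureImportance(list(ids), model.feature_gain.copy(),
                             model.feature_split_count.copy())


def training_loss(model: BoostedModel, X, y,
                  upto: int | None = None) -> float:
    """Objective value on (X, y) using the first ``upto`` iterations."""
    Xa, _, _ = _resolve_X(X)
    y = np.asarray(y)
    n = Xa.shape[0]
    K = model.n_classes
    n_iter = model.n_iterations if upto is None else upto
    if K == 1:
        raw = np.full(n, model.base_score[0])
        for tree in model.trees[:n_iter]:
            raw += tree.predict(Xa)
        if model.objective == "l2":
            return float(0.5 * np.mean((raw - y.astype(float)) ** 2))
        prob = np.clip(_sigmoid(raw), 1e-15, 1 - 1e-15)
        yt = y.astype(float)
        return float(-np.mean(yt * np.log(prob) + (1 - yt) * np.log(1 - prob)))
    raw = np.tile(model.base_score, (n, 1))
    for tree in model.trees[: n_iter * K]:
        raw[:, tree.class_index] += tree.predict(Xa)
    prob = np.clip(_softmax(raw), 1e-15, None)
    ycode = np.array([model.classes_.index(v) for v in y.tolist()])
    return float(-np.mean(np.log(prob[np.arange(n), ycode])))


# ---------------------------------------------------------------------------
# Grid search


def grid_search(X, y, param_grid: dict, cv_folds: int = 5, seed: int = 0,
                objective: str = "l2"):
    """Exhaustive hyperparameter search under k-fold cross-validation.

    Scores each Cartesian-grid point by mean Pearson r (regression) or mean
    AUC (classification) over the folds; ties go to the first point in grid
    order. Returns ``(best_params, table)`` where ``table`` is a list of
    (params, mean_score) in grid order.
    """
    from .metrics import pearson_r, binary_auc, multiclass_ovr_auc

    if not param_grid:
        raise ValueError("empty parameter grid")
    if cv_folds < 2:
        raise ValueError("need at least 2 folds")
    Xa, _, _ = _resolve_X(X)
    y = np.asarray(y)
    n = Xa.shape[0]
    if n // cv_folds < 2:
        raise ValueError("folds would have fewer than 2 samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, cv_folds)

    keys = list(param_grid)
    table = []
    best = None
    for combo in itertools.product(*(param_grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        scores = []
        for f in range(cv_folds):
            test_idx = folds[f]
            train_idx = np.concatenate(
                [folds[g] for g in range(cv_folds) if g != f])
            model = fit(Xa[train_idx], y[train_idx], objective=objective,
                        **params)
            pred = predict(model, Xa[test_idx])
            if objective == "l2":
                scores.append(pearson_r(y[test_idx].astype(float), pred))
            elif objective == "binary":
                scores.append(binary_auc(y[test_idx].astype(int), pred))
            else:
                aucs = multiclass_ovr_auc(
                    np.array([model.classes_.index(v)
                              for v in y[test_idx].tolist()]), pred)
                scores.append(float(np.nanmean(aucs)))
        mean_score = float(np.mean(scores))
        table.append((params, mean_score))
        if best is None or mean_score > best[1]:
            best = (params, mean_score)
    return best[0], table
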