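"""Classification trees with Gini impurity and oblique splits.

Splits are linear combinations ``sum_j c_j x_j <= t`` (the ``<=`` side
routes LEFT). Coefficients are found by cyclic coordinate descent started
from the best axis-parallel split, with seeded random restarts and backward
deletion of near-zero coefficients, so the search space always contains the
axis splits and the returned split is never worse than the best of them.
Trees are grown to purity and pruned by minimal cost-complexity with
stratified k-fold cross-validation and the 1-SE rule. The published fixed
two-splitter tree is provided as :func:`published_tree`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seldi_nodal.spectra_io import NODE_NEGATIVE, NODE_POSITIVE

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------

@dataclass
class SplitNode:
    node_id: int
    coefficients: dict  # feature name -> weight; at least one nonzero
    threshold: float
    left_child: int
    right_child: int

    def __post_init__(self) -> None:
        if not any(v != 0 for v in self.coefficients.values()):
            raise ValueError("split needs at least one nonzero coefficient")

    def value(self, sample) -> float:
        total = 0.0
        for feat, coef in self.coefficients.items():
            try:
                x = sample[feat]
            except (KeyError, IndexError):
                raise KeyError(
                    f"sample is missing feature {feat!r} required by the model"
                ) from None
            total += coef * float(x)
        return total


@dataclass
class LeafNode:
    node_id: int
    label: str
    training_counts: dict = field(default_factory=dict)


@dataclass
class TreeModel:
    nodes: dict
    root_id: int
    training_meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.root_id not in self.nodes:
            raise ValueError("root_id not among nodes")
        seen = set()
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise ValueError(f"cycle or shared node at id {nid}")
            seen.add(nid)
            node = self.nodes.get(nid)
            if node is None:
                raise ValueError(f"dangling child id {nid}")
            if isinstance(node, SplitNode):
                stack.extend([node.left_child, node.right_child])
        if seen != set(self.nodes):
            raise ValueError("disconnected nodes present")

    def features(self) -> list:
        feats = set()
        for node in self.nodes.values():
            if isinstance(node, SplitNode):
                feats.update(k for k, v in node.coefficients.items() if v != 0)
        return sorted(feats)

    @property
    def n_leaves(self) -> int:
        return sum(isinstance(n, LeafNode) for n in self.nodes.values())

    @property
    def n_splits(self) -> int:
        return sum(isinstance(n, SplitNode) for n in self.nodes.values())


@dataclass
class TreeParams:
    max_depth: int | None = None
    min_node_size: int = 5
    allow_oblique: bool = True
    n_restarts: int = 20
    max_cycles: int = 5
    class_priors: dict | None = None
    misclassification_costs: dict | None = None
    cv_folds: int = 10
    prune: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


# ---------------------------------------------------------------------------
# Impurity and split search
# ---------------------------------------------------------------------------

def gini_impurity(class_counts, class_weights=None) -> float:
    """1 - sum p_k^2 over (optionally reweighted) class counts."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be >= 0")
    if class_weights is not None:
        counts = counts * np.asarray(class_weights, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("gini impurity undefined for all-zero counts")
    p = counts / total
    return float(1.0 - np.dot(p, p))


def _gini_rows(counts: np.ndarray) -> np.ndarray:
    """Gini of each row of a (m, K) count matrix (0 where the row is empty)."""
    tot = counts.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / tot[..., None]
        g = 1.0 - np.einsum("...k,...k->...", p, p)
    return np.where(tot > 0, g, 0.0)


def _decrease_for_left(left: np.ndarray, Y: np.ndarray,
                       parent_gini: float) -> np.ndarray:
    """Impurity decrease for each candidate left-mask row of ``left``."""
    total = Y.sum(axis=0)
    W = total.sum()
    cl = left.astype(float) @ Y            # (m, K)
    cr = total[None, :] - cl
    wl = cl.sum(axis=1)
    wr = cr.sum(axis=1)
    return parent_gini - (wl * _gini_rows(cl) + wr * _gini_rows(cr)) / W


def _axis_scan(v: np.ndarray, Y: np.ndarray, parent_gini: float) -> tuple:
    """Best threshold on projection ``v``: (threshold, decrease).

    Thresholds are midpoints between consecutive distinct sorted values;
    ties in decrease break toward the smaller threshold. Returns
    (None, 0.0) for a constant projection.
    """
    order = np.argsort(v, kind="stable")
    vs = v[order]
    Ys = Y[order]
    boundaries = np.flatnonzero(np.diff(vs) > 0)
    if boundaries.size == 0:
        return None, 0.0
    cum = np.cumsum(Ys, axis=0)
    total = cum[-1]
    W = total.sum()
    cl = cum[boundaries]
    cr = total[None, :] - cl
    wl = cl.sum(axis=1)
    wr = cr.sum(axis=1)
    dec = parent_gini - (wl * _gini_rows(cl) + wr * _gini_rows(cr)) / W
    best = int(np.argmax(dec))  # first max -> smallest threshold
    thr = 0.5 * (vs[boundaries[best]] + vs[boundaries[best] + 1])
    return float(thr), float(dec[best])


def best_axis_split(X, y, feature) -> tuple:
    """Best single-feature threshold split: (threshold, impurity_decrease)."""
    X, names, y_codes, _ = _coerce_xy(X, y)
    j = names.index(feature) if isinstance(feature, str) else int(feature)
    Y = _onehot(y_codes)
    parent = gini_impurity(Y.sum(axis=0))
    return _axis_scan(X[:, j], Y, parent)


def _onehot(y_codes: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    K = n_classes or (int(y_codes.max()) + 1 if len(y_codes) else 0)
    Y = np.zeros((len(y_codes), K))
    Y[np.arange(len(y_codes)), y_codes] = 1.0
    return Y


def best_oblique_split(X, y, candidate_features=None, params: TreeParams = None,
                       rng: np.random.Generator = None) -> tuple:
    """Search for the best linear-combination split.

    Returns (coefficients, threshold, impurity_decrease) with the
    coefficient vector scaled to unit maximum magnitude; coefficients are a
    dict over feature names. The returned decrease is never below the best
    axis-parallel decrease. With no impurity-decreasing split, returns
    (None, None, 0.0).
    """
    params = params or TreeParams()
    X, names, y_codes, _ = _coerce_xy(X, y)
    if candidate_features is not None:
        idx = [names.index(f) if isinstance(f, str) else int(f)
               for f in candidate_features]
        X = X[:, idx]
        names = [names[i] for i in idx]
    rng = rng or np.random.default_rng(params.seed)
    Y = _onehot(y_codes)
    coef, thr, dec = _oblique_search(X, Y, params, rng)
    if coef is None:
        return None, None, 0.0
    return ({n: float(c) for n, c in zip(names, coef)}, float(thr), float(dec))


def _oblique_search(X: np.ndarray, Y: np.ndarray, params: TreeParams,
                    rng: np.random.Generator) -> tuple:
    """Coordinate-descent search; returns (coef array, threshold, decrease)."""
    n, d = X.shape
    parent = gini_impurity(Y.sum(axis=0))
    if parent == 0:
        return None, None, 0.0

    # axis-parallel baseline over every feature
    axis_best = (None, None, 0.0)  # (j, thr, dec)
    for j in range(d):
        thr, dec = _axis_scan(X[:, j], Y, parent)
        if thr is not None and dec > axis_best[2] + _EPS:
            axis_best = (j, thr, dec)
    if axis_best[0] is None:
        return None, None, 0.0

    best_coef = np.zeros(d)
    best_coef[axis_best[0]] = 1.0
    best_thr = axis_best[1]
    best_dec = axis_best[2]

    if params.allow_oblique and d > 1:
        for restart in range(params.n_restarts):
            if best_dec >= parent - _EPS:
                break  # already a perfect split
            if restart == 0:
                coef = best_coef.copy()
                thr = best_thr
            else:
                coef = rng.standard_normal(d)
                coef /= max(np.max(np.abs(coef)), _EPS)
                thr, dec0 = _axis_scan(X @ coef, Y, parent)
                if thr is None:
                    continue
            coef, thr, dec = _coordinate_descent(X, Y, coef, thr, parent, params)
            if dec > best_dec + _EPS:
                best_coef, best_thr, best_dec = coef, thr, dec

    best_coef, best_thr, best_dec = _backward_delete(
        X, Y, best_coef, best_thr, best_dec, parent)

    scale = np.max(np.abs(best_coef))
    best_coef = best_coef / scale
    best_thr = best_thr / scale
    return best_coef, best_thr, best_dec


def _coordinate_descent(X, Y, coef, thr, parent, params) -> tuple:
    n, d = X.shape
    joint = n <= 32  # small nodes: rescan the threshold per candidate
    v = X @ coef
    _, dec = _axis_scan_fixed(v, Y, thr, parent)
    for _ in range(params.max_cycles):
        improved = False
        for j in range(d):
            xj = X[:, j]
            nz = np.abs(xj) > _EPS
            if not nz.any():
                continue
            r = v - coef[j] * xj
            u = (thr - r[nz]) / xj[nz]
            u = np.unique(u)
            cand = [u[0] - 1.0, u[-1] + 1.0, 0.0]
            if u.size > 1:
                cand.extend(0.5 * (u[:-1] + u[1:]))
            cand = np.asarray(cand)
            if joint:
                for c in cand:
                    t_c, dec_c = _axis_scan(r + c * xj, Y, parent)
                    if t_c is not None and dec_c > dec + _EPS:
                        coef = coef.copy()
                        coef[j] = c
                        v = r + c * xj
                        thr, dec = t_c, dec_c
                        improved = True
            else:
                left = (np.outer(cand, xj) + r[None, :]) <= thr + _EPS
                decs = _decrease_for_left(left, Y, parent)
                b = int(np.argmax(decs))
                if decs[b] > dec + _EPS:
                    coef = coef.copy()
                    coef[j] = cand[b]
                    v = r + coef[j] * xj
                    dec = decs[b]
                    improved = True
        new_thr, new_dec = _axis_scan(v, Y, parent)
        if new_thr is not None and new_dec > dec + _EPS:
            thr, dec = new_thr, new_dec
            improved = True
        if not improved or dec >= parent - _EPS:
            break
    return coef, thr, dec


def _axis_scan_fixed(v, Y, thr, parent) -> tuple:
    left = (v <= thr)[None, :]
    return thr, float(_decrease_for_left(left, Y, parent)[0])


def _backward_delete(X, Y, coef, thr, dec, parent) -> tuple:
    """Zero out small coefficients when doing so costs no impurity decrease."""
    active = np.flatnonzero(coef)
    order = active[np.argsort(np.abs(coef[active]))]
    for j in order:
        if np.count_nonzero(coef) <= 1:
            break
        trial = coef.copy()
        trial[j] = 0.0
        new_thr, new_dec = _axis_scan(X @ trial, Y, parent)
        if new_thr is not None and new_dec >= dec - _EPS:
            coef, thr, dec = trial, new_thr, new_dec
    return coef, thr, dec


# ---------------------------------------------------------------------------
# Growing, pruning, predicting
# ---------------------------------------------------------------------------

class _BNode:
    """Mutable builder node used during growth and pruning."""

    __slots__ = ("coef", "threshold", "left", "right", "counts", "decrease")

    def __init__(self, counts):
        self.coef = None
        self.threshold = None
        self.left = None
        self.right = None
        self.counts = counts
        self.decrease = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.coef is None

    def majority(self) -> int:
        return int(np.argmax(self.counts))  # first max -> lowest class index

    def leaf_error(self) -> float:
        return float(self.counts.sum() - self.counts.max())

    def subtree_error(self) -> float:
        if self.is_leaf:
            return self.leaf_error()
        return self.left.subtree_error() + self.right.subtree_error()

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()


def _coerce_xy(X, y=None):
    """Accept PeakMatrix / DataFrame / ndarray; return (X, names, codes, classes)."""
    from seldi_nodal.peak_detection import PeakMatrix

    if isinstance(X, PeakMatrix):
        if y is None:
            y = X.labels
        names = X.feature_names
        X = X.values
    elif isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X = X.to_numpy(float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    if y is None:
        raise ValueError("labels required")
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    codes = np.array([classes.index(v) for v in y])
    return X, names, codes, classes


def _grow(X, Y, params, rng, depth) -> _BNode:
    node = _BNode(Y.sum(axis=0))
    n = len(X)
    pure = np.count_nonzero(node.counts) <= 1
    if (pure or n < params.min_node_size
            or (params.max_depth is not None and depth >= params.max_depth)):
        return node
    coef, thr, dec = _oblique_search(X, Y, params, rng) if params.allow_oblique \
        else _axis_only(X, Y)
    if coef is None or dec <= _EPS:
        return node
    left = X @ coef <= thr
    if not left.any() or left.all():  # degenerate partition: refuse
        return node
    node.coef, node.threshold, node.decrease = coef, thr, dec
    node.left = _grow(X[left], Y[left], params, rng, depth + 1)
    node.right = _grow(X[~left], Y[~left], params, rng, depth + 1)
    return node


def _axis_only(X, Y):
    parent = gini_impurity(Y.sum(axis=0))
    best = (None, None, 0.0)
    for j in range(X.shape[1]):
        thr, dec = _axis_scan(X[:, j], Y, parent)
        if thr is not None and dec > best[2] + _EPS:
            coef = np.zeros(X.shape[1])
            coef[j] = 1.0
            best = (coef, thr, dec)
    return best


def _route(node: _BNode, X: np.ndarray) -> np.ndarray:
    """Predicted class index for each row of X under a builder tree."""
    out = np.empty(len(X), dtype=int)
    stack = [(node, np.arange(len(X)))]
    while stack:
        nd, idx = stack.pop()
        if nd.is_leaf:
            out[idx] = nd.majority()
            continue
        left = X[idx] @ nd.coef <= nd.threshold
        stack.append((nd.left, idx[left]))
        stack.append((nd.right, idx[~left]))
    return out


# --- minimal cost-complexity pruning ---------------------------------------

def _prune_sequence(root: _BNode) -> list:
    """Weakest-link sequence [(alpha, tree)] from the full tree to the root."""
    seq = [(0.0, copy.deepcopy(root))]
    current = copy.deepcopy(root)
    while not current.is_leaf:
        links = []

        def visit(nd):
            if nd.is_leaf:
                return
            g = (nd.leaf_error() - nd.subtree_error()) / (nd.n_leaves() - 1)
            links.append((g, nd))
            visit(nd.left)
            visit(nd.right)

        visit(current)
        alpha = min(g for g, _ in links)
        for g, nd in links:
            if g <= alpha + _EPS and not nd.is_leaf:
                nd.coef = None
                nd.left = nd.right = None
        seq.append((max(alpha, 0.0), copy.deepcopy(current)))
    return seq


def _prune_at(root: _BNode, alpha: float) -> _BNode:
    """Smallest subtree of ``root`` whose weakest link exceeds ``alpha``."""
    tree = copy.deepcopy(root)
    while not tree.is_leaf:
        links = []

        def visit(nd):
            if nd.is_leaf:
                return
            g = (nd.leaf_error() - nd.subtree_error()) / (nd.n_leaves() - 1)
            links.append((g, nd))
            visit(nd.left)
            visit(nd.right)

        visit(tree)
        weakest = min(g for g, _ in links)
        if weakest > alpha + _EPS:
            break
        for g, nd in links:
            if g <= alpha + _EPS and not nd.is_leaf:
                nd.coef = None
                nd.left = nd.right = None
    return tree


def _stratified_folds(y_codes: np.ndarray, k: int,
                      rng: np.random.Generator) -> list:
    folds = [[] for _ in range(k)]
    for cls in np.unique(y_codes):
        idx = np.flatnonzero(y_codes == cls)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.array(sorted(f)) for f in folds]


def _cv_choose_alpha(X, Y, y_codes, params, rng, main_seq) -> float:
    alphas = [a for a, _ in main_seq]
    # one representative alpha per subtree: the geometric mean of its
    # interval [a_k, a_k+1), and a_m itself for the last (root) tree
    reps = []
    for k, a in enumerate(alphas):
        if k + 1 < len(alphas):
            reps.append(float(np.sqrt(max(a, _EPS) * max(alphas[k + 1], _EPS))))
        else:
            reps.append(a)
    k = params.cv_folds
    folds = _stratified_folds(y_codes, k, rng)
    errors = np.zeros(len(reps))
    n = len(X)
    for f in folds:
        mask = np.ones(n, dtype=bool)
        mask[f] = False
        if len(np.unique(y_codes[mask])) < 2 or len(f) == 0:
            raise ValueError("cross-validation fold with a single class; "
                             "reduce cv_folds")
        fold_tree = _grow(X[mask], Y[mask], params,
                          np.random.default_rng(params.seed + 7919), 0)
        for r, alpha in enumerate(reps):
            pruned = _prune_at(fold_tree, alpha)
            pred = _route(pruned, X[f])
            errors[r] += np.sum(pred != y_codes[f])
    rates = errors / n
    best = int(np.argmin(rates))
    se = float(np.sqrt(rates[best] * (1 - rates[best]) / n))
    chosen = best
    for r in range(len(reps) - 1, best, -1):
        if rates[r] <= rates[best] + se:
            chosen = r
            break
    return reps[chosen]


def fit_tree(X, y=None, params: TreeParams = None, seed: int | None = None) -> TreeModel:
    """Grow (and optionally prune) an oblique classification tree.

    Growth continues to purity / ``min_node_size`` / ``max_depth``; with
    ``params.prune`` the grown tree is cut back by minimal cost-complexity
    pruning, the penalty chosen by stratified ``cv_folds``-fold
    cross-validation with the 1-SE rule. Deterministic given the seed.
    """
    params = params or TreeParams()
    Xa, names, y_codes, classes = _coerce_xy(X, y)
    if len(Xa) == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    Y = _onehot(y_codes, n_classes=len(classes))
    if params.class_priors or params.misclassification_costs:
        freq = Y.sum(axis=0) / len(Y)
        w = np.ones(len(classes))
        if params.class_priors:
            w *= np.array([params.class_priors.get(c, freq[k])
                           for k, c in enumerate(classes)]) / freq
        if params.misclassification_costs:
            w *= np.array([params.misclassification_costs.get(c, 1.0)
                           for c in classes])
        Y = Y * w
    root = _grow(Xa, Y, params, rng, 0)
    if params.prune and not root.is_leaf and len(classes) > 1:
        seq = _prune_sequence(root)
        if len(seq) > 1:
            alpha = _cv_choose_alpha(Xa, Y, y_codes, params, rng, seq)
            root = _prune_at(root, alpha)
    return _to_model(root, names, classes,
                     meta={"params": {k: v for k, v in vars(params).items()
                                      if not isinstance(v, dict) or v},
                           "seed": params.seed if seed is None else seed})


def _to_model(root: _BNode, names, classes, meta=None) -> TreeModel:
    nodes = {}
    next_id = [1]

    def build(nd: _BNode) -> int:
        nid = next_id[0]
        next_id[0] += 1
        if nd.is_leaf:
            counts = {cls: int(c) for cls, c in zip(classes, nd.counts)}
            nodes[nid] = LeafNode(node_id=nid, label=classes[nd.majority()],
                                  training_counts=counts)
            return nid
        coefficients = {names[j]: float(c) for j, c in enumerate(nd.coef)
                        if c != 0.0}
        placeholder = SplitNode(node_id=nid, coefficients=coefficients,
                                threshold=float(nd.threshold),
                                left_child=-1, right_child=-1)
        nodes[nid] = placeholder
        placeholder.left_child = build(nd.left)
        placeholder.right_child = build(nd.right)
        return nid

    root_id = build(root)
    model = TreeModel(nodes=nodes, root_id=root_id, training_meta=meta or {})
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Prediction, importance, cross-validation, the published tree
# ---------------------------------------------------------------------------

def predict(model: TreeModel, sample) -> tuple:
    """Route one sample; returns (class label, visited node ids)."""
    path = []
    nid = model.root_id
    while True:
        path.append(nid)
        node = model.nodes[nid]
        if isinstance(node, LeafNode):
            return node.label, path
        nid = node.left_child if node.value(sample) <= node.threshold \
            else node.right_child


def predict_matrix(model: TreeModel, X) -> list:
    """Predicted labels for a PeakMatrix / DataFrame of feature columns."""
    from seldi_nodal.peak_detection import PeakMatrix

    if isinstance(X, PeakMatrix):
        df = pd.DataFrame(X.values, columns=X.feature_names)
    elif isinstance(X, pd.DataFrame):
        df = X
    else:
        raise TypeError("predict_matrix needs a PeakMatrix or DataFrame")
    return [predict(model, row)[0] for row in df.to_dict("records")]


def variable_importance(model: TreeModel, X, y=None) -> dict:
    """Per-feature importance scaled so the top feature scores exactly 100.

    Each split node contributes its (data-weighted) impurity decrease,
    shared across its features proportionally to coefficient magnitude.
    """
    Xa, names, y_codes, classes = _coerce_xy(X, y)
    Y = _onehot(y_codes, n_classes=len(classes))
    n_total = len(Xa)
    scores = {f: 0.0 for f in names}
    for f in model.features():
        scores.setdefault(f, 0.0)

    def visit(nid, idx):
        node = model.nodes[nid]
        if isinstance(node, LeafNode) or len(idx) == 0:
            return
        v = np.array([node.value(dict(zip(names, Xa[i]))) for i in idx])
        left = v <= node.threshold
        counts = Y[idx].sum(axis=0)
        parent = gini_impurity(counts)
        dec = float(_decrease_for_left(left[None, :], Y[idx], parent)[0])
        weight = len(idx) / n_total * max(dec, 0.0)
        total_mag = sum(abs(c) for c in node.coefficients.values())
        if total_mag > 0:
            for feat, c in node.coefficients.items():
                scores[feat] = scores.get(feat, 0.0) + weight * abs(c) / total_mag
        visit(node.left_child, idx[left])
        visit(node.right_child, idx[~left])

    visit(model.root_id, np.arange(n_total))
    top = max(scores.values(), default=0.0)
    if top <= 0:
        return {f: 0.0 for f in scores}
    return {f: 100.0 * s / top for f, s in scores.items()}


def cross_validate(X, y=None, params: TreeParams = None,
                   seed: int | None = None):
    """Stratified k-fold cross-validation; pooled confusion counts.

    Each fold's model is fit with ``params`` on the remaining folds and
    evaluated on the held-out fold. Returns a PerformanceReport (mode
    ``cv``) with per-fold reports attached.
    """
    from seldi_nodal.evaluation import compute_metrics

    params = params or TreeParams()
    Xa, names, y_codes, classes = _coerce_xy(X, y)
    k = params.cv_folds
    counts = np.bincount(y_codes)
    if k > counts.min():
        raise ValueError(f"cv_folds={k} exceeds the smallest class count "
                         f"({counts.min()})")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    folds = _stratified_folds(y_codes, k, rng)
    truth_all, pred_all = [], []
    fold_reports = []
    df = pd.DataFrame(Xa, columns=names)
    y_arr = np.array([classes[c] for c in y_codes])
    for f in folds:
        mask = np.ones(len(Xa), dtype=bool)
        mask[f] = False
        if len(np.unique(y_codes[f])) < 2 or len(np.unique(y_codes[mask])) < 2:
            raise ValueError("stratification failed: fold with a single class")
        model = fit_tree(df[mask], y_arr[mask], params=params)
        preds = predict_matrix(model, df.iloc[f])
        truth = y_arr[f].tolist()
        fold_reports.append(compute_metrics(preds, truth, mode="cv"))
        truth_all.extend(truth)
        pred_all.extend(preds)
    pooled = compute_metrics(pred_all, truth_all, mode="cv")
    pooled.fold_reports = fold_reports
    return pooled


PUBLISHED_FEATURES = ("mz_3104", "mz_3781", "mz_5867", "mz_7970", "mz_9290")


def published_tree() -> TreeModel:
    """The fixed two-splitter, three-leaf tree with the published weights.

    Node 1 splits on the five-peak linear combination at threshold 1.122;
    its LEFT child is Node 2 (threshold 0.248 over two peaks). Terminal
    Nodes 1 and 3 are node-positive, Terminal Node 2 node-negative. Of the
    two candidate placements of Node 2, only this one routes each class's
    published mean intensity vector to a terminal of its own class.
    """
    nodes = {
        1: SplitNode(
            node_id=1,
            coefficients={"mz_3104": -0.075, "mz_3781": -0.231,
                          "mz_5867": 0.157, "mz_7970": 0.086,
                          "mz_9290": 0.953},
            threshold=1.122, left_child=2, right_child=3),
        2: SplitNode(
            node_id=2,
            coefficients={"mz_3781": 0.410, "mz_5867": -0.912},
            threshold=0.248, left_child=4, right_child=5),
        3: LeafNode(node_id=3, label=NODE_POSITIVE,
                    training_counts={}),  # Terminal Node 3
        4: LeafNode(node_id=4, label=NODE_POSITIVE,
                    training_counts={}),  # Terminal Node 1
        5: LeafNode(node_id=5, label=NODE_NEGATIVE,
                    training_counts={}),  # Terminal Node 2
    }
    model = TreeModel(nodes=nodes, root_id=1,
                      training_meta={"source": "published", "fixed": True})
    model.validate()
    return model
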