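"""Coarse decision-tree signature classifier.

A CART-style tree capped at three binary splits (four leaves), grown
best-first with Gini's diversity index and no surrogate splits. Candidate
thresholds sit at midpoints between consecutive distinct sorted feature
values; a sample with feature value >= threshold goes right.

Determinism: impurity decreases are compared in exact rational arithmetic, so
ties are genuine ties, and they are broken by fixed rules independent of the
row order of the training table: first the split whose threshold lies in the
widest value gap relative to the node's feature range (the most robust
boundary), then the lowest feature index, then the lowest threshold. Leaf
labels are the majority class, ties going to the class with the larger
training prior and then to the canonical class order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .core_io import FEATURE_NAMES, SIGNATURES, FeatureVector
from .cohort_stats import CohortSummary

__all__ = [
    "gini_impurity",
    "TreeNode",
    "SignatureTree",
    "train_coarse_tree",
    "predict_signature",
    "TrainValSplit",
    "ValidationReport",
    "run_model_selection",
    "classify_cohort",
]

#: Training/validation class sizes of the reference protocol.
DEFAULT_TRAIN_COUNTS = {"control": 25, "ataxia": 20, "dystonia": 20, "tremor": 20}
DEFAULT_VAL_COUNTS = {"control": 8, "ataxia": 4, "dystonia": 4, "tremor": 4}

_MARGIN_TIE_TOL = 1e-12


def gini_impurity(class_counts) -> float:
    """Gini's diversity index, 1 - sum(p_k^2)."""
    c = np.asarray(class_counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative class count")
    n = c.sum()
    if n == 0:
        raise ValueError("all-zero class counts")
    p = c / n
    return float(1.0 - np.sum(p * p))


@dataclass
class TreeNode:
    """Internal node (feature, threshold, children) or leaf (label)."""

    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: str | None = None
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.label, "class_counts": self.class_counts}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "class_counts": self.class_counts,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "leaf" in d:
            return cls(label=d["leaf"], class_counts=dict(d.get("class_counts", {})))
        return cls(feature=d["feature"], threshold=float(d["threshold"]),
                   class_counts=dict(d.get("class_counts", {})),
                   left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]))


@dataclass
class SignatureTree:
    """A fitted coarse tree mapping a feature vector to a signature label."""

    root: TreeNode
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    # -- structure ---------------------------------------------------------
    def _internal_nodes(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            if not n.is_leaf:
                out.append(n)
                stack.extend([n.left, n.right])
        return out

    @property
    def n_splits(self) -> int:
        return len(self._internal_nodes())

    def features_used(self) -> tuple[str, ...]:
        """Distinct split features in order of first use (breadth-first)."""
        seen: list[str] = []
        queue = [self.root]
        while queue:
            n = queue.pop(0)
            if not n.is_leaf:
                if n.feature not in seen:
                    seen.append(n.feature)
                queue.extend([n.left, n.right])
        return tuple(seen)

    # -- prediction --------------------------------------------------------
    def predict_one(self, x) -> str:
        """Descend the tree for one sample (FeatureVector, mapping, or array)."""
        if isinstance(x, FeatureVector):
            x = x.as_dict()
        if isinstance(x, np.ndarray):
            x = dict(zip(self.feature_names, x))
        node = self.root
        while not node.is_leaf:
            v = x.get(node.feature)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(f"missing feature {node.feature!r} "
                                 "(no surrogate splits)")
            node = node.left if v < node.threshold else node.right
        return node.label

    def predict(self, X) -> list[str]:
        if isinstance(X, pd.DataFrame):
            return [self.predict_one(row.to_dict()) for _, row in X.iterrows()]
        return [self.predict_one(x) for x in X]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "classes": list(self.classes),
            "metadata": self.metadata,
            "root": self.root.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureTree":
        return cls(root=TreeNode.from_dict(d["root"]),
                   feature_names=tuple(d["feature_names"]),
                   classes=tuple(d["classes"]),
                   metadata=dict(d.get("metadata", {})))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _canonical_classes(labels) -> tuple[str, ...]:
    present = set(labels)
    known = [s for s in SIGNATURES if s in present]
    extra = sorted(present - set(SIGNATURES))
    return tuple(known + extra)


def _weighted_gini_sum(sq_sum: int, n: int) -> Fraction:
    """n * gini(counts) = n - sum(c^2)/n, as an exact rational."""
    return Fraction(n) - Fraction(sq_sum, n)


@dataclass
class _Candidate:
    decrease: Fraction
    margin: float
    feature_idx: int
    threshold: float
    split_at: int          # left side = first `split_at` samples in sort order
    order: np.ndarray      # sort order of node rows for this feature


def _best_split(Xn: np.ndarray, yn: np.ndarray, n_classes: int
                ) -> _Candidate | None:
    """Best (feature, threshold) for one node; None if no split helps."""
    n, n_feat = Xn.shape
    counts = np.bincount(yn, minlength=n_classes)
    parent = _weighted_gini_sum(int(np.sum(counts.astype(object) ** 2)), n)
    best: _Candidate | None = None
    for f in range(n_feat):
        v = Xn[:, f]
        order = np.argsort(v, kind="stable")
        vs, ys = v[order], yn[order]
        rng_v = vs[-1] - vs[0]
        if rng_v == 0:
            continue
        left = np.zeros(n_classes, dtype=np.int64)
        sq_left = 0
        for i in range(n - 1):
            c = ys[i]
            sq_left += 2 * left[c] + 1
            left[c] += 1
            if vs[i + 1] <= vs[i]:
                continue
            right = counts - left
            sq_right = int(np.sum(right.astype(object) ** 2))
            child = (_weighted_gini_sum(sq_left, i + 1)
                     + _weighted_gini_sum(sq_right, n - i - 1))
            dec = parent - child
            if dec <= 0:
                continue
            thr = (vs[i] + vs[i + 1]) / 2.0
            margin = (vs[i + 1] - vs[i]) / rng_v
            cand = _Candidate(dec, margin, f, thr, i + 1, order)
            if best is None or _better(cand, best):
                best = cand
    return best


def _better(a: _Candidate, b: _Candidate) -> bool:
    """Fixed preference order: decrease, then margin, feature index, threshold."""
    if a.decrease != b.decrease:
        return a.decrease > b.decrease
    if abs(a.margin - b.margin) > _MARGIN_TIE_TOL:
        return a.margin > b.margin
    if a.feature_idx != b.feature_idx:
        return a.feature_idx < b.feature_idx
    return a.threshold < b.threshold


def _leaf_label(counts: np.ndarray, priors: np.ndarray, classes) -> str:
    """Majority class; ties -> larger training prior, then canonical order."""
    best = 0
    for k in range(1, len(classes)):
        if (counts[k], priors[k]) > (counts[best], priors[best]):
            best = k
    return classes[best]


def train_coarse_tree(
    features,
    labels=None,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    max_splits: int = 3,
    metadata: dict | None = None,
) -> SignatureTree:
    """Fit the coarse tree by best-first greedy growth.

    ``features`` may be a list of :class:`FeatureVector` (labels taken from
    ``group_label`` unless given), a DataFrame, or a 2-D array with explicit
    ``labels``. At each step the (leaf, feature, threshold) combination with
    the largest weighted Gini decrease anywhere in the tree is split, until
    ``max_splits`` splits have been made or no split decreases impurity.
    """
    if isinstance(features, pd.DataFrame):
        X = features[list(feature_names)].to_numpy(float)
        y_raw = list(labels)
    elif len(features) and isinstance(features[0], FeatureVector):
        X = np.vstack([f.values() for f in features])
        feature_names = FEATURE_NAMES
        y_raw = list(labels) if labels is not None else [f.group_label for f in features]
    else:
        X = np.asarray(features, dtype=float)
        y_raw = list(labels)
    if np.isnan(X).any():
        raise ValueError("missing feature values")
    classes = _canonical_classes(y_raw)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to train")
    class_idx = {c: k for k, c in enumerate(classes)}
    y = np.array([class_idx[l] for l in y_raw], dtype=np.int64)
    priors = np.bincount(y, minlength=len(classes))

    def node_counts(idx: np.ndarray) -> dict[str, int]:
        c = np.bincount(y[idx], minlength=len(classes))
        return {cl: int(c[k]) for k, cl in enumerate(classes) if c[k]}

    all_idx = np.arange(len(y))
    root = TreeNode(class_counts=node_counts(all_idx))
    # Leaves eligible for expansion: (creation order, node, row indices).
    frontier: list[tuple[int, TreeNode, np.ndarray]] = [(0, root, all_idx)]
    created = 1
    for _ in range(max_splits):
        best_leaf = None
        best_cand = None
        for entry in frontier:
            _, _, idx = entry
            cand = _best_split(X[idx], y[idx], len(classes))
            if cand is None:
                continue
            # Decrease is weighted by node size implicitly: _best_split returns
            # the decrease in (n * gini) summed over the node, which is the
            # tree-wide weighted decrease times the total sample count.
            if best_cand is None or _node_better(cand, entry[0], best_cand, best_leaf[0]):
                best_cand, best_leaf = cand, entry
        if best_cand is None:
            break
        order_pos, node, idx = best_leaf
        sorted_idx = idx[best_cand.order]
        left_idx = np.sort(sorted_idx[:best_cand.split_at])
        right_idx = np.sort(sorted_idx[best_cand.split_at:])
        node.feature = feature_names[best_cand.feature_idx]
        node.threshold = float(best_cand.threshold)
        node.left = TreeNode(class_counts=node_counts(left_idx))
        node.right = TreeNode(class_counts=node_counts(right_idx))
        frontier.remove(best_leaf)
        frontier.append((created, node.left, left_idx))
        frontier.append((created + 1, node.right, right_idx))
        created += 2

    # Label remaining leaves.
    for _, node, idx in frontier:
        c = np.bincount(y[idx], minlength=len(classes))
        node.label = _leaf_label(c, priors, classes)

    md = dict(metadata or {})
    md.setdefault("class_counts", {c: int(priors[k]) for k, c in enumerate(classes)})
    tree = SignatureTree(root=root, feature_names=tuple(feature_names),
                         classes=classes, metadata=md)
    md["training_accuracy"] = float(np.mean(
        np.array(tree.predict(pd.DataFrame(X, columns=list(feature_names)))) ==
        np.array(y_raw)))
    return tree


def _node_better(cand: _Candidate, order: int, best: _Candidate, best_order: int) -> bool:
    """Compare candidates across leaves; leaf creation order is the last tie-break."""
    if cand.decrease != best.decrease:
        return cand.decrease > best.decrease
    if abs(cand.margin - best.margin) > _MARGIN_TIE_TOL:
        return cand.margin > best.margin
    if cand.feature_idx != best.feature_idx:
        return cand.feature_idx < best.feature_idx
    if cand.threshold != best.threshold:
        return cand.threshold < best.threshold
    return order < best_order


def predict_signature(tree: SignatureTree, feature_vector) -> str:
    """Assign a signature label by threshold descent ('<' left, '>=' right)."""
    return tree.predict_one(feature_vector)


# ---------------------------------------------------------------------------
# Train/validation selection protocol
# ---------------------------------------------------------------------------

@dataclass
class TrainValSplit:
    split_id: int
    train_idx: dict[str, np.ndarray]
    val_idx: dict[str, np.ndarray]
    seed: int


@dataclass
class ValidationReport:
    splits: list[TrainValSplit]
    trees: list[SignatureTree]
    accuracies: list[float]
    selected: int              # index into the split list
    rationale: str

    @property
    def selected_tree(self) -> SignatureTree:
        return self.trees[self.selected]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s, t, a in zip(self.splits, self.trees, self.accuracies):
            rows.append({
                "split_id": s.split_id,
                "val_accuracy": a,
                "n_splits": t.n_splits,
                "features_used": "|".join(t.features_used()),
                "selected": int(s.split_id == self.splits[self.selected].split_id),
            })
        return pd.DataFrame(rows)


def run_model_selection(
    features: list[FeatureVector],
    labels=None,
    n_splits: int = 12,
    seed: int = 0,
    train_counts: dict[str, int] | None = None,
    val_counts: dict[str, int] | None = None,
) -> ValidationReport:
    """Train ``n_splits`` coarse trees on stratified random partitions and
    select the best-validating model.

    Each split draws, per class and without replacement, the stated number of
    training and validation cells from an RNG stream derived from
    ``(seed, split_id)``. The selected model maximizes validation accuracy;
    ties prefer fewer distinct split features, then the lower split id.
    """
    train_counts = dict(train_counts or DEFAULT_TRAIN_COUNTS)
    val_counts = dict(val_counts or DEFAULT_VAL_COUNTS)
    y = np.array(labels if labels is not None else [f.group_label for f in features])
    by_class = {c: np.flatnonzero(y == c) for c in train_counts}
    for c, idx in by_class.items():
        need = train_counts[c] + val_counts.get(c, 0)
        if idx.size < need:
            raise ValueError(f"class {c!r} has {idx.size} cells, needs {need}")

    splits, trees, accs = [], [], []
    for sid in range(1, n_splits + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, sid]))
        tr_idx, va_idx = {}, {}
        for c, idx in by_class.items():
            perm = rng.permutation(idx)
            tr_idx[c] = np.sort(perm[:train_counts[c]])
            va_idx[c] = np.sort(perm[train_counts[c]:train_counts[c] + val_counts[c]])
        tr = np.concatenate([tr_idx[c] for c in train_counts])
        va = np.concatenate([va_idx[c] for c in train_counts])
        tree = train_coarse_tree([features[i] for i in tr], labels=list(y[tr]),
                                 metadata={"split_id": sid, "seed": seed})
        pred = [tree.predict_one(features[i]) for i in va]
        acc = float(np.mean(np.array(pred) == y[va]))
        splits.append(TrainValSplit(sid, tr_idx, va_idx, seed))
        trees.append(tree)
        accs.append(acc)

    def rank(i: int):
        return (-accs[i], len(trees[i].features_used()), splits[i].split_id)

    selected = min(range(n_splits), key=rank)
    rationale = (f"split {splits[selected].split_id}: accuracy {accs[selected]:.3f}, "
                 f"{len(trees[selected].features_used())} distinct features")
    return ValidationReport(splits, trees, accs, selected, rationale)


def classify_cohort(tree: SignatureTree, features: list[FeatureVector]
                    ) -> CohortSummary:
    """Assign signatures to every cell and tabulate origin group x signature."""
    if not features:
        raise ValueError("empty cohort")
    origins = [f.group_label or "unlabeled" for f in features]
    assigned = [tree.predict_one(f) for f in features]
    return CohortSummary.from_assignments(origins, assigned)
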