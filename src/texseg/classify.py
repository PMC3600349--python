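"""KNN voxel classification and the decision-tree-of-KNNs (DTKNN).

The classifier is a binary tree whose nodes are k-nearest-neighbour
classifiers, each restricted to at most three features chosen by
exhaustive search to maximize AUC90 (the area under the leave-one-out
ROC at specificity above 0.9).  Training samples predicted abnormal and
normal at a node are routed to separate branches; a branch that still
contains misclassified samples receives its own KNN node as long as both
classes keep at least ``min_class_samples`` samples there and the
addition strictly improves whole-tree leave-one-out accuracy.

Features are standardized (training mean subtracted, divided by the
training standard deviation) once per model; zero-variance features are
dropped.  Distances are Euclidean over the node's feature subset, with
distance ties at the k-th neighbour resolved by stable sample order.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ABNORMAL = "abnormal"
NORMAL = "normal"


# --------------------------------------------------------------------
# samples and standardization


@dataclass
class TrainingSample:
    """One slice-averaged ROI sample: a named feature vector plus label."""

    features: dict[str, float]
    label: str  # "abnormal" | "normal"
    patient_id: str = ""
    slice_index: int = -1
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.label not in (ABNORMAL, NORMAL):
            raise ValueError(f"label must be abnormal/normal, got {self.label!r}")


def samples_to_frame(samples: Sequence[TrainingSample]) -> tuple[pd.DataFrame, np.ndarray]:
    """Stack samples into a feature DataFrame and a boolean abnormal vector."""
    X = pd.DataFrame([s.features for s in samples])
    if X.isna().any().any():
        raise ValueError("samples have missing features")
    y = np.array([s.label == ABNORMAL for s in samples])
    return X, y


def samples_to_csv(samples: Sequence[TrainingSample], path) -> None:
    rows = []
    for s in samples:
        row = {
            "label": s.label,
            "patient_id": s.patient_id,
            "slice_index": s.slice_index,
            "tissue": s.tissue,
        }
        row.update(s.features)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def samples_from_csv(path) -> list[TrainingSample]:
    df = pd.read_csv(path)
    meta = ["label", "patient_id", "slice_index", "tissue"]
    feats = [c for c in df.columns if c not in meta]
    out = []
    for _, row in df.iterrows():
        out.append(
            TrainingSample(
                features={c: float(row[c]) for c in feats},
                label=str(row["label"]),
                patient_id=str(row.get("patient_id", "")),
                slice_index=int(row.get("slice_index", -1)),
                tissue=str(row.get("tissue", "")),
            )
        )
    return out


@dataclass
class Standardizer:
    """Per-feature training mean/std; zero-variance features are dropped."""

    means: pd.Series
    stds: pd.Series

    @property
    def features(self) -> list[str]:
        return list(self.means.index)

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "Standardizer":
        means = X.mean()
        stds = X.std(ddof=1)
        keep = stds > 0
        if not keep.all():
            dropped = list(stds.index[~keep])
            warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
        return cls(means=means[keep], stds=stds[keep])

    def transform(
        self, X: pd.DataFrame | Mapping[str, float], features: Sequence[str] | None = None
    ) -> pd.DataFrame:
        """Standardize the retained features (or a subset of them)."""
        if isinstance(X, Mapping):
            X = pd.DataFrame([X])
        feats = list(features) if features is not None else self.features
        unknown = [f for f in feats if f not in self.features]
        if unknown:
            raise KeyError(f"features without standardization statistics: {unknown}")
        missing = [f for f in feats if f not in X.columns]
        if missing:
            raise KeyError(f"missing features: {missing}")
        return (X[feats] - self.means[feats]) / self.stds[feats]


# --------------------------------------------------------------------
# KNN node


@dataclass
class KNNNode:
    """A KNN classifier over a subset of at most three features.

    ``X`` holds the standardized node training samples restricted to the
    subset; ``sample_idx`` maps rows back to the model-level sample index
    so leave-one-out evaluation can exclude the queried sample wherever
    it appears.  ``children[True]`` / ``children[False]`` are the
    abnormal- / normal-predicted branches (``None`` = leaf side).
    """

    features: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    sample_idx: np.ndarray
    k: int = 7
    roc: "ROCCurve | None" = None
    children: dict = field(default_factory=lambda: {True: None, False: None})

    def __post_init__(self) -> None:
        if not 1 <= len(self.features) <= 3:
            raise ValueError("feature subset size must be 1-3")
        if self.k % 2 == 0:
            raise ValueError("k must be odd")
        if self.y.all() or not self.y.any():
            raise ValueError("node needs samples from both classes")


def _effective_k(k: int, n_train: int) -> int:
    ke = min(k, n_train)
    if ke % 2 == 0:
        ke -= 1
    return max(ke, 1)


def _knn_counts(node: KNNNode, x: np.ndarray, exclude: int | None = None):
    """Abnormal-vote count among the k nearest node samples to ``x``."""
    X, y = node.X, node.y
    if exclude is not None:
        keep = node.sample_idx != exclude
        X, y = X[keep], y[keep]
    if X.shape[0] == 0:
        raise ValueError("node has no training samples")
    d2 = np.sum((X - x) ** 2, axis=1)
    ke = _effective_k(node.k, X.shape[0])
    order = np.argsort(d2, kind="stable")[:ke]
    n_a = int(np.count_nonzero(y[order]))
    return n_a, ke


def knn_predict(
    x: np.ndarray | Mapping[str, float],
    node: KNNNode,
    exclude: int | None = None,
) -> tuple[str, float]:
    """Classify a standardized feature vector at one KNN node.

    Returns the majority class among the k nearest training samples and
    the vote fraction ``max(n_a, n_n) / k`` as confidence.
    """
    if isinstance(x, Mapping):
        x = np.array([x[f] for f in node.features], dtype=np.float64)
    n_a, ke = _knn_counts(node, np.asarray(x, dtype=np.float64), exclude)
    label = ABNORMAL if 2 * n_a > ke else NORMAL
    return label, max(n_a, ke - n_a) / ke


def knn_score(
    x: np.ndarray, node: KNNNode, exclude: int | None = None
) -> float:
    """ROC score: fraction of the k nearest neighbours that are abnormal."""
    n_a, ke = _knn_counts(node, x, exclude)
    return n_a / ke


# --------------------------------------------------------------------
# LOOCV ROC / AUC90


@dataclass
class ROCCurve:
    """Operating points (specificity, sensitivity) over vote thresholds."""

    points: np.ndarray  # (m, 2) columns: specificity, sensitivity
    thresholds: np.ndarray
    auc: float
    auc90: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise ValueError("AUC outside [0, 1]")
        if not 0.0 <= self.auc90 <= 0.1 + 1e-12:
            raise ValueError("AUC90 outside [0, 0.1]")


def roc_from_scores(scores: np.ndarray, y: np.ndarray, k: int = 7) -> ROCCurve:
    """ROC over the ``k + 1`` possible vote-fraction thresholds plus endpoints."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes")
    thresholds = np.concatenate([[np.inf], np.arange(k, -1, -1) / k])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = scores >= t
        sens[i] = np.count_nonzero(pred & y) / n_pos
        spec[i] = np.count_nonzero(~pred & ~y) / n_neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    # area restricted to specificity in [0.9, 1]  (fpr in [0, 0.1])
    cut = 0.1
    inside = fpr <= cut
    fx = np.concatenate([fpr[inside], [cut]])
    fy = np.concatenate([sens[inside], [np.interp(cut, fpr, sens)]])
    auc90 = float(np.trapezoid(fy, fx))
    return ROCCurve(
        points=np.column_stack([spec, sens]),
        thresholds=thresholds,
        auc=min(max(auc, 0.0), 1.0),
        auc90=min(max(auc90, 0.0), cut),
    )


def _loocv_scores(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Leave-one-out abnormal-vote fractions via a full distance matrix."""
    n = X.shape[0]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    ke = _effective_k(k, n - 1)
    order = np.argsort(d2, axis=1, kind="stable")[:, :ke]
    return y[order].sum(axis=1) / ke


def loocv_roc(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    features: Sequence[str] | None = None,
    k: int = 7,
) -> ROCCurve:
    """Leave-one-out ROC of a single KNN over a feature subset.

    Each sample is scored by the abnormal-vote fraction among its k
    nearest neighbours with itself excluded.
    """
    if isinstance(X, pd.DataFrame):
        A = X[list(features)].to_numpy(dtype=np.float64) if features else X.to_numpy(np.float64)
    else:
        A = np.asarray(X, dtype=np.float64)
        if A.ndim == 1:
            A = A[:, None]
    y = np.asarray(y, dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    scores = _loocv_scores(A, y, k)
    return roc_from_scores(scores, y, k=_effective_k(k, A.shape[0] - 1))


def search_best_subset(
    X: pd.DataFrame,
    y: np.ndarray,
    candidates: Sequence[str] | None = None,
    max_size: int = 3,
    k: int = 7,
) -> tuple[tuple[str, ...], ROCCurve]:
    """Exhaustive search over all feature subsets of size 1..max_size.

    Returns the subset with the highest LOOCV AUC90.  AUC90 ties (common
    when several subsets separate the samples perfectly) are broken by
    the full AUC, then in favour of smaller subsets, then lexicographic
    name order (the iteration order, combined with a strict-improvement
    rule).
    """
    if candidates is None:
        candidates = list(X.columns)
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("no candidate features")
    best: tuple[tuple[str, ...], ROCCurve] | None = None
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(candidates, size):
            roc = loocv_roc(X, y, subset, k=k)
            if (
                best is None
                or roc.auc90 > best[1].auc90 + 1e-12
                or (
                    abs(roc.auc90 - best[1].auc90) <= 1e-12
                    and roc.auc > best[1].auc + 1e-12
                )
            ):
                best = (subset, roc)
    return best


# --------------------------------------------------------------------
# DTKNN


@dataclass
class DTKNNConfig:
    k: int = 7
    max_subset: int = 3
    min_class_samples: int = 4  # stop growing when a branch class falls below
    candidate_pool: int | None = None  # cap on features entering the search
    candidates: tuple[str, ...] | None = None


@dataclass
class DTKNNModel:
    root: KNNNode
    standardizer: Standardizer
    config: DTKNNConfig
    feature_names: tuple[str, ...]

    @property
    def manifest(self) -> tuple[str, ...]:
        """Union of the feature subsets used anywhere in the tree."""
        names: list[str] = []

        def visit(node: KNNNode | None):
            if node is None:
                return
            for f in node.features:
                if f not in names:
                    names.append(f)
            visit(node.children[True])
            visit(node.children[False])

        visit(self.root)
        return tuple(names)

    def depth(self) -> int:
        def d(node: KNNNode | None) -> int:
            if node is None:
                return 0
            return 1 + max(d(node.children[True]), d(node.children[False]))

        return d(self.root)


def _fit_node(
    Xs: pd.DataFrame, y: np.ndarray, idx: np.ndarray, cfg: DTKNNConfig,
    candidates: Sequence[str],
) -> KNNNode:
    subset, roc = search_best_subset(
        Xs.iloc[idx], y[idx], candidates, max_size=cfg.max_subset, k=cfg.k
    )
    return KNNNode(
        features=subset,
        X=Xs.iloc[idx][list(subset)].to_numpy(np.float64),
        y=y[idx],
        sample_idx=np.asarray(idx),
        k=cfg.k,
        roc=roc,
    )


def _route_loocv(node: KNNNode, Xs: pd.DataFrame) -> np.ndarray:
    """Leave-one-out abnormal predictions of a node for its own samples."""
    pred = np.empty(node.sample_idx.size, dtype=bool)
    sub = list(node.features)
    for row, i in enumerate(node.sample_idx):
        x = Xs.iloc[i][sub].to_numpy(np.float64)
        label, _ = knn_predict(x, node, exclude=i)
        pred[row] = label == ABNORMAL
    return pred


def tree_loocv_predict(root: KNNNode, Xs: pd.DataFrame) -> np.ndarray:
    """Whole-tree leave-one-out predictions for every training sample."""
    n = len(Xs)
    out = np.empty(n, dtype=bool)
    for i in range(n):
        node = root
        while True:
            x = Xs.iloc[i][list(node.features)].to_numpy(np.float64)
            label, _ = knn_predict(x, node, exclude=i)
            p = label == ABNORMAL
            child = node.children[p]
            if child is None:
                out[i] = p
                break
            node = child
    return out


def train_dtknn(
    samples: Sequence[TrainingSample] | tuple[pd.DataFrame, np.ndarray],
    config: DTKNNConfig | None = None,
) -> DTKNNModel:
    """Grow a DTKNN from labelled ROI samples.

    The root node is fitted on all samples; samples are then routed by
    each node's leave-one-out prediction, and a child is added to a
    branch only when the branch contains misclassified samples, both
    classes retain at least ``min_class_samples`` there, and attaching
    the child strictly improves whole-tree leave-one-out accuracy.
    """
    cfg = config or DTKNNConfig()
    if isinstance(samples, tuple):
        X, y = samples
    else:
        X, y = samples_to_frame(samples)
    if y.all() or not y.any():
        raise ValueError("training data must contain both classes")
    std = Standardizer.fit(X)
    Xs = std.transform(X)

    candidates = list(cfg.candidates) if cfg.candidates else list(Xs.columns)
    if cfg.candidate_pool is not None and cfg.candidate_pool < len(candidates):
        # rank features by single-feature AUC90 and keep the strongest
        def rank_key(f: str):
            r = loocv_roc(Xs, y, [f], k=cfg.k)
            return (-r.auc90, -r.auc, f)

        ranked = sorted(candidates, key=rank_key)
        candidates = sorted(ranked[: cfg.candidate_pool])

    all_idx = np.arange(len(Xs))
    root = _fit_node(Xs, y, all_idx, cfg, candidates)

    def accuracy() -> float:
        return float(np.mean(tree_loocv_predict(root, Xs) == y))

    def grow(node: KNNNode) -> None:
        pred = _route_loocv(node, Xs)
        for side in (True, False):
            branch_idx = node.sample_idx[pred == side]
            if branch_idx.size == 0:
                continue
            yb = y[branch_idx]
            mis = np.any(yb != side)
            if not mis:
                continue
            if yb.sum() < cfg.min_class_samples or (~yb).sum() < cfg.min_class_samples:
                continue
            acc_before = accuracy()
            child = _fit_node(Xs, y, branch_idx, cfg, candidates)
            node.children[side] = child
            if accuracy() > acc_before + 1e-12:
                grow(child)
            else:
                node.children[side] = None

    grow(root)
    return DTKNNModel(
        root=root, standardizer=std, config=cfg, feature_names=tuple(Xs.columns)
    )


def dtknn_predict(
    x: Mapping[str, float] | pd.Series, model: DTKNNModel
) -> tuple[str, float]:
    """Classify one raw (unstandardized) feature vector with the tree.

    ``x`` must cover at least the model manifest (the features the tree
    actually uses)."""
    xd = dict(x)
    feats = model.manifest if not all(f in xd for f in model.standardizer.features) else None
    xs = model.standardizer.transform(xd, features=feats).iloc[0]
    node = model.root
    while True:
        label, conf = knn_predict(xs[list(node.features)].to_numpy(np.float64), node)
        child = node.children[label == ABNORMAL]
        if child is None:
            return label, conf
        node = child


def dtknn_predict_batch(X: pd.DataFrame, model: DTKNNModel) -> np.ndarray:
    """Boolean abnormal predictions for a DataFrame of raw feature vectors.

    ``X`` may carry just the model manifest columns."""
    feats = model.manifest if not all(f in X.columns for f in model.standardizer.features) else None
    Xs = model.standardizer.transform(X, features=feats)
    out = np.empty(len(Xs), dtype=bool)
    for i in range(len(Xs)):
        node = model.root
        row = Xs.iloc[i]
        while True:
            label, _ = knn_predict(row[list(node.features)].to_numpy(np.float64), node)
            p = label == ABNORMAL
            child = node.children[p]
            if child is None:
                out[i] = p
                break
            node = child
    return out


# --------------------------------------------------------------------
# serialization


def _node_to_dict(node: KNNNode | None) -> dict | None:
    if node is None:
        return None
    return {
        "features": list(node.features),
        "X": node.X.tolist(),
        "y": node.y.astype(int).tolist(),
        "sample_idx": node.sample_idx.tolist(),
        "k": node.k,
        "children": {
            "abnormal": _node_to_dict(node.children[True]),
            "normal": _node_to_dict(node.children[False]),
        },
    }


def _node_from_dict(d: dict | None) -> KNNNode | None:
    if d is None:
        return None
    node = KNNNode(
        features=tuple(d["features"]),
        X=np.asarray(d["X"], dtype=np.float64),
        y=np.asarray(d["y"], dtype=bool),
        sample_idx=np.asarray(d["sample_idx"], dtype=np.intp),
        k=int(d["k"]),
    )
    node.children = {
        True: _node_from_dict(d["children"]["abnormal"]),
        False: _node_from_dict(d["children"]["normal"]),
    }
    return node


def save_model(model: DTKNNModel, path) -> None:
    doc = {
        "format": "texseg-dtknn",
        "version": 1,
        "feature_names": list(model.feature_names),
        "standardizer": {
            "features": model.standardizer.features,
            "means": model.standardizer.means.tolist(),
            "stds": model.standardizer.stds.tolist(),
        },
        "config": {
            "k": model.config.k,
            "max_subset": model.config.max_subset,
            "min_class_samples": model.config.min_class_samples,
            "candidate_pool": model.config.candidate_pool,
            "candidates": list(model.config.candidates) if model.config.candidates else None,
        },
        "tree": _node_to_dict(model.root),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> DTKNNModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "texseg-dtknn":
        raise ValueError("not a texseg DTKNN model file")
    std = Standardizer(
        means=pd.Series(doc["standardizer"]["means"], index=doc["standardizer"]["features"]),
        stds=pd.Series(doc["standardizer"]["stds"], index=doc["standardizer"]["features"]),
    )
    cfgd = doc["config"]
    cfg = DTKNNConfig(
        k=cfgd["k"],
        max_subset=cfgd["max_subset"],
        min_class_samples=cfgd["min_class_samples"],
        candidate_pool=cfgd["candidate_pool"],
        candidates=tuple(cfgd["candidates"]) if cfgd["candidates"] else None,
    )
    return DTKNNModel(
        root=_node_from_dict(doc["tree"]),
        standardizer=std,
        config=cfg,
        feature_names=tuple(doc["feature_names"]),
    )
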