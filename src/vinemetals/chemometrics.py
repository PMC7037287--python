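"""Geographic-origin chemometrics: LDA with cross-validation and
hierarchical clustering of element profiles.

Observations are element-concentration vectors (one row per sample), the
class label is the sampling area.  Features are z-scored before the
discriminant fit so the axes are invariant to per-element rescaling.
Clustering defaults to Ward linkage on Euclidean distances of z-scored
profiles, with Newick export of the resulting ultrametric tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.linalg import LinAlgError
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from skbio import TreeNode

#: elements with discriminatory power for must/wine origin (Co excluded:
#: all-censored in beverages)
DEFAULT_LDA_ELEMENTS = ("Cr", "Hg", "As", "Cu", "Zn", "Pb", "Ni", "Cd")


@dataclass
class DiscriminantModel:
    classes: list[str]
    explained_pct: np.ndarray       # per discriminant axis, non-increasing
    scores: np.ndarray              # observations projected on the axes
    class_means_projected: np.ndarray
    scalings: np.ndarray
    feature_names: list[str] | None = None


def _zscore(X: np.ndarray, mean=None, sd=None):
    mean = X.mean(axis=0) if mean is None else mean
    sd = X.std(axis=0, ddof=0) if sd is None else sd
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def _as_matrix(features) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    return np.asarray(features, dtype=float), None


def lda_fit(features, labels, standardize: bool = True) -> DiscriminantModel:
    """Fisher discriminant axes with explained-variance percentages.

    Priors are proportional to class counts.  A singular within-class
    scatter matrix is rejected with advice to drop collinear elements.
    """
    X, names = _as_matrix(features)
    y = np.asarray(labels)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if len(y) <= len(classes):
        raise ValueError("need more observations than classes")
    if standardize:
        X, _, _ = _zscore(X)
    model = LinearDiscriminantAnalysis(solver="eigen")
    try:
        with np.errstate(all="ignore"):
            model.fit(X, y)
        scores = model.transform(X)
    except (LinAlgError, np.linalg.LinAlgError) as err:
        raise ValueError(
            "singular within-class scatter; drop collinear elements "
            "or add observations"
        ) from err
    if not np.all(np.isfinite(scores)):
        raise ValueError("singular within-class scatter; drop collinear elements")
    evr = model.explained_variance_ratio_
    n_axes = min(len(classes) - 1, X.shape[1])
    explained = 100.0 * evr[:n_axes] / evr[:n_axes].sum()
    class_means = np.vstack([scores[y == c].mean(axis=0) for c in classes])
    return DiscriminantModel(classes, explained, scores[:, :n_axes],
                             class_means[:, :n_axes], model.scalings_, names)


def crossvalidate(features, labels, scheme: str = "leave_one_out",
                  k: int = 5, standardize: bool = True,
                  seed: int | None = None) -> tuple[pd.DataFrame, float]:
    """Held-out LDA classification: (confusion matrix, accuracy %).

    Each observation is predicted by a model fitted without it
    (leave-one-out) or without its fold (stratified k-fold).  Folds that
    would lose an entire class are rejected.
    """
    X, _ = _as_matrix(features)
    y = np.asarray(labels)
    classes = sorted(set(y))
    if scheme == "leave_one_out":
        splitter = LeaveOneOut()
    elif scheme == "k_fold":
        counts = pd.Series(y).value_counts()
        if counts.min() < k:
            raise ValueError(f"{k}-fold split would lose a class (min class size {counts.min()})")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for train, test in splitter.split(X, y):
        if len(set(y[train])) < len(classes):
            raise ValueError("a fold lost an entire class; use fewer folds")
        Xtr, Xte = X[train], X[test]
        if standardize:
            Xtr, mean, sd = _zscore(Xtr)
            Xte, _, _ = _zscore(Xte, mean, sd)
        model = LinearDiscriminantAnalysis(solver="svd").fit(Xtr, y[train])
        for true, pred in zip(y[test], model.predict(Xte)):
            confusion.loc[true, pred] += 1
    accuracy = 100.0 * np.trace(confusion.to_numpy()) / confusion.to_numpy().sum()
    return confusion, float(accuracy)


# ------------------------------------------------------------- clustering

@dataclass
class ClusterResult:
    labels: list[str]
    linkage_matrix: np.ndarray

    def cut(self, k: int) -> dict[str, int]:
        """Cluster id per item when the tree is cut into ``k`` clusters."""
        assignment = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_tree(self) -> TreeNode:
        """The dendrogram as a tree with branch lengths summing to merge heights."""
        root, _ = hierarchy.to_tree(self.linkage_matrix, rd=True)

        def build(node) -> TreeNode:
            if node.is_leaf():
                return TreeNode(name=self.labels[node.id])
            children = [build(node.left), build(node.right)]
            for child, raw in zip(children, (node.left, node.right)):
                child.length = node.dist - raw.dist
            return TreeNode(children=children)

        tree = build(root)
        tree.length = 0.0
        return tree

    def to_newick(self) -> str:
        return str(self.to_tree())


def hcluster(profiles: pd.DataFrame, metric: str = "euclidean",
             linkage: str = "ward", standardize: bool = True) -> ClusterResult:
    """Agglomerative clustering of item × feature profiles.

    Ties are broken deterministically by input order (scipy's convention).
    Non-finite cells are rejected; impute censored values upstream.
    """
    X = profiles.to_numpy(dtype=float)
    if len(X) < 2:
        raise ValueError("need at least two items to cluster")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite cells in profile matrix")
    if standardize:
        X, _, _ = _zscore(X)
    Z = hierarchy.linkage(X, method=linkage, metric=metric)
    return ClusterResult([str(i) for i in profiles.index], Z)


def soil_profile_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Site×depth rows by element columns, ready for :func:`hcluster`."""
    soil = records[records["compartment"] == "soil"]
    wide = soil.pivot_table(index=["area", "depth_cm"], columns="element",
                            values="value", sort=False)
    wide.index = [f"{a} {d}" for a, d in wide.index]
    return wide


def impute_censored(records: pd.DataFrame, loq: dict[str, float],
                    fraction: float = 0.5) -> pd.DataFrame:
    """Replace censored zeros by ``fraction``·LOQ for multivariate stages."""
    out = records.copy()
    mask = out["censored"]
    out.loc[mask, "value"] = [loq.get(el, 0.0) * fraction for el in out.loc[mask, "element"]]
    return out
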