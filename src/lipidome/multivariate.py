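"""Multivariate procedures: Ward clustering, PLS-DA, and MCCV biomarker ROC.

These reproduce, as reusable library calls, the unsupervised and
supervised analyses typically run interactively in metabolomics suites:

* **Hierarchical clustering** of samples with Euclidean distances and
  the Ward.D2 criterion (squared-distance Lance–Williams update on
  unsquared Euclidean input, i.e. R's ``hclust(method="ward.D2")`` /
  SciPy's ``linkage(method="ward")``).
* **PLS-DA** with a two-latent-variable model on a 0/1 class indicator:
  in-fit R², leave-one-out Q² = 1 − PRESS/TSS, and leave-one-out
  nearest-class accuracy.
* **Multivariate exploratory ROC** by Monte-Carlo cross-validation:
  each round draws a balanced subsample (majority class downsampled to
  the minority size), splits it 2/3 train / 1/3 validation, fits a
  random forest for both classification and feature ranking, and
  records validation AUC.  Candidate panels of size k are refit per
  round on the top-k features ranked by that round's training-data
  importances — validation samples never inform the panel they are
  scored on — and the per-size AUCs are averaged over rounds.  The
  reported overall ranking and selected panel use mean importance over
  all rounds.  All randomness flows from one seed.

AUC uses the Mann–Whitney formulation with ties counted 1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier

from lipidome.preprocess import IntensityMatrix

__all__ = [
    "ClusterResult",
    "PLSDAReport",
    "BiomarkerReport",
    "ward_cluster",
    "plsda",
    "rf_biomarker_mccv",
    "roc_auc",
]


def _complete_case_samples_by_lipids(m: IntensityMatrix) -> pd.DataFrame:
    """Samples × lipids design matrix; lipids with missing peaks dropped."""
    x = m.values.T
    incomplete = x.columns[x.isna().any(axis=0)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} lipid(s) with missing values",
            stacklevel=3,
        )
        x = x.drop(columns=incomplete)
    if x.shape[1] == 0:
        raise ValueError("no complete-case lipids left")
    return x


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples (Euclidean / Ward.D2)."""

    merges: list[tuple[int, int]]
    heights: list[float]
    leaf_order: list[int]
    labels: list[str]
    linkage_matrix: np.ndarray
    distance: str = "euclidean"
    linkage: str = "ward.D2"

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster assignment per sample at ``n_clusters`` clusters."""
        flat = hierarchy.fcluster(
            self.linkage_matrix, t=n_clusters, criterion="maxclust"
        )
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge-height branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def ward_cluster(m: IntensityMatrix) -> ClusterResult:
    """Cluster samples with Euclidean distance and the Ward.D2 criterion.

    Expects a log2-median matrix.  Merge heights are monotone
    non-decreasing; ties resolve deterministically.
    """
    if m.state != "log2_median":
        raise ValueError(f"clustering expects log2_median state, got {m.state!r}")
    x = _complete_case_samples_by_lipids(m)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    z = hierarchy.linkage(x.to_numpy(dtype=float), method="ward")
    return ClusterResult(
        merges=[(int(a), int(b)) for a, b in z[:, :2]],
        heights=[float(h) for h in z[:, 2]],
        leaf_order=[int(i) for i in hierarchy.leaves_list(z)],
        labels=list(x.index),
        linkage_matrix=z,
    )


@dataclass
class PLSDAReport:
    """Two-component PLS-DA fit with leave-one-out validation."""

    n_components: int
    scores: pd.DataFrame  # samples × components
    accuracy: float  # leave-one-out nearest-class accuracy
    r2: float  # in-fit fraction of label variance explained
    q2: float  # leave-one-out 1 - PRESS/TSS
    classes: tuple[str, str] = ("0", "1")


def _autoscale(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _pls_fit_predict(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray, k: int
) -> np.ndarray:
    mu, sd = x_train.mean(axis=0), x_train.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    k = min(k, x_train.shape[0] - 1, x_train.shape[1])
    model = PLSRegression(n_components=k, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit((x_train - mu) / sd, y_train.astype(float))
        pred = model.predict((x_test - mu) / sd)
    return np.asarray(pred).ravel()


def plsda(m: IntensityMatrix, labels, n_components: int = 2) -> PLSDAReport:
    """PLS discriminant analysis of a two-class design.

    ``labels`` maps sample → class (mapping or Series); the
    second-sorted class is encoded 1.  Features are autoscaled (mean 0,
    unit variance) inside every fit.  Requires ≥ 3 samples per class.
    """
    labels = pd.Series(labels).reindex(m.sample_ids)
    if labels.isna().any():
        raise ValueError("every sample needs a class label")
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"PLS-DA needs exactly 2 classes, got {classes}")
    y = (labels == classes[1]).to_numpy(dtype=float)
    if y.sum() < 3 or (1 - y).sum() < 3:
        raise ValueError("each class needs at least 3 samples")
    x = _complete_case_samples_by_lipids(m)
    xv = x.to_numpy(dtype=float)

    k = min(n_components, xv.shape[0] - 1, xv.shape[1])
    model = PLSRegression(n_components=k, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(_autoscale(xv), y)
        fitted = np.asarray(model.predict(_autoscale(xv))).ravel()
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - fitted) ** 2).sum()) / tss

    press = 0.0
    correct = 0
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        pred = _pls_fit_predict(xv[keep], y[keep], xv[[i]], n_components)[0]
        press += (y[i] - pred) ** 2
        correct += int((pred >= 0.5) == bool(y[i]))
    q2 = 1.0 - press / tss
    scores = pd.DataFrame(
        model.x_scores_,
        index=x.index,
        columns=[f"LV{i + 1}" for i in range(k)],
    )
    return PLSDAReport(
        n_components=k,
        scores=scores,
        accuracy=correct / len(y),
        r2=r2,
        q2=q2,
        classes=(str(classes[0]), str(classes[1])),
    )


def roc_auc(scores, labels) -> float:
    """ROC AUC by the Mann–Whitney rank formulation; ties count 1/2.

    ``labels`` are truthy for the positive class; higher scores should
    indicate the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class BiomarkerReport:
    """MCCV random-forest feature ranking and panel performance."""

    ranking: pd.DataFrame  # lipid, mean_importance (descending)
    panel_auc: dict[int, tuple[float, float, float]]  # size -> (mean, lo, hi)
    full_model_auc: float
    accuracy: float  # validation accuracy at the selected panel
    selected_panel: list[str]
    panel_size: int
    n_rounds: int
    seed: int
    n_trees: int = 500
    max_features: str = "sqrt"
    round_aucs: dict[int, list[float]] = field(default_factory=dict)


def _balanced_split(
    rng: np.random.Generator, idx_pos: np.ndarray, idx_neg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced subsample then stratified 2/3 train / 1/3 validation."""
    n = min(len(idx_pos), len(idx_neg))
    pos = rng.permutation(idx_pos)[:n]
    neg = rng.permutation(idx_neg)[:n]
    n_train = max(int(round(n * 2 / 3)), 1)
    if n_train == n:  # keep at least one validation sample per class
        n_train = n - 1
    train = np.concatenate([pos[:n_train], neg[:n_train]])
    valid = np.concatenate([pos[n_train:], neg[n_train:]])
    return train, valid


def rf_biomarker_mccv(
    m: IntensityMatrix,
    labels,
    panel_sizes: tuple[int, ...] = (5, 10, 15, 25),
    n_rounds: int = 100,
    seed: int = 0,
    panel_size: int = 15,
    n_trees: int = 500,
) -> BiomarkerReport:
    """Monte-Carlo cross-validated random-forest biomarker analysis.

    Each of ``n_rounds`` rounds draws a balanced subsample, splits it
    2/3 train / 1/3 validation (stratified), fits a random forest
    (``n_trees`` trees, √p features per split) on all lipids for
    feature ranking and validation AUC, then refits every candidate
    panel size on the top-k lipids of that round's own training-data
    ranking (validation never informs its panel).  The reported overall
    ranking is by mean importance over rounds; per-panel AUC is the
    across-round mean with a 2.5–97.5 percentile interval; accuracy is
    validation accuracy at the selected ``panel_size``.
    Bit-reproducible from ``seed``.
    """
    labels = pd.Series(labels).reindex(m.sample_ids)
    if labels.isna().any():
        raise ValueError("every sample needs a class label")
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"biomarker analysis needs 2 classes, got {classes}")
    y = (labels == classes[1]).to_numpy()
    if y.sum() < 3 or (~y).sum() < 3:
        raise ValueError("each class needs at least 3 samples")
    if n_rounds < 10:
        warnings.warn(
            f"n_rounds={n_rounds} gives unstable rankings; use >= 10",
            stacklevel=2,
        )
    x = _complete_case_samples_by_lipids(m)
    lipids = list(x.columns)
    bad = [k for k in panel_sizes if k > len(lipids)]
    if bad or panel_size > len(lipids):
        raise ValueError(f"panel size(s) exceed the {len(lipids)} lipids")
    if panel_size not in panel_sizes:
        panel_sizes = tuple(sorted(set(panel_sizes) | {panel_size}))
    xv = x.to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    round_states = rng.integers(0, 2**31 - 1, size=n_rounds)
    idx_pos = np.flatnonzero(y)
    idx_neg = np.flatnonzero(~y)

    splits = []
    importances = np.zeros((n_rounds, len(lipids)))
    full_aucs = []
    for r in range(n_rounds):
        r_rng = np.random.default_rng(round_states[r])
        train, valid = _balanced_split(r_rng, idx_pos, idx_neg)
        splits.append((train, valid))
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(round_states[r]),
            n_jobs=1,
        )
        rf.fit(xv[train], y[train])
        importances[r] = rf.feature_importances_
        prob = rf.predict_proba(xv[valid])[:, list(rf.classes_).index(True)]
        full_aucs.append(roc_auc(prob, y[valid]))

    mean_imp = importances.mean(axis=0)
    order = sorted(range(len(lipids)), key=lambda i: (-mean_imp[i], lipids[i]))
    ranking = pd.DataFrame(
        {
            "lipid": [lipids[i] for i in order],
            "mean_importance": [float(mean_imp[i]) for i in order],
        }
    )

    # Per-round feature order from that round's training fit only, so the
    # panel refits never see information from their validation samples.
    round_orders = [
        sorted(range(len(lipids)), key=lambda i: (-importances[r][i], lipids[i]))
        for r in range(n_rounds)
    ]

    panel_auc: dict[int, tuple[float, float, float]] = {}
    round_aucs: dict[int, list[float]] = {}
    accuracy = float("nan")
    for k in sorted(panel_sizes):
        aucs = []
        accs = []
        for r, (train, valid) in enumerate(splits):
            cols = np.array(round_orders[r][:k])
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=int(round_states[r]),
                n_jobs=1,
            )
            rf.fit(xv[np.ix_(train, cols)], y[train])
            prob = rf.predict_proba(xv[np.ix_(valid, cols)])[
                :, list(rf.classes_).index(True)
            ]
            aucs.append(roc_auc(prob, y[valid]))
            accs.append(float(np.mean((prob >= 0.5) == y[valid])))
        round_aucs[k] = aucs
        panel_auc[k] = (
            float(np.mean(aucs)),
            float(np.percentile(aucs, 2.5)),
            float(np.percentile(aucs, 97.5)),
        )
        if k == panel_size:
            accuracy = float(np.mean(accs))

    return BiomarkerReport(
        ranking=ranking,
        panel_auc=panel_auc,
        full_model_auc=float(np.mean(full_aucs)),
        accuracy=accuracy,
        selected_panel=list(ranking["lipid"].head(panel_size)),
        panel_size=panel_size,
        n_rounds=n_rounds,
        seed=seed,
        n_trees=n_trees,
        round_aucs=round_aucs,
    )
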