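"""Weighted correlation network analysis of the feature table.

Follows the WGCNA methodology: soft-threshold adjacency from pairwise
Pearson correlations, topological overlap similarity, average-linkage
hierarchical clustering of the TOM dissimilarity into modules, module
eigengenes (first principal component of each module), eigengene-network
adjacency A_IJ = (1 + cor(E_I, E_J))/2, and module preservation between a
reference and a test cohort defined as P = 1 - |A_ref - A_test| with
per-module column means summarising how well each module's relationships
to all others are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .containers import FeatureTable

logger = logging.getLogger("progmet")


# ------------------------------------------------------------ correlations
def _log_matrix(table: FeatureTable) -> np.ndarray:
    """samples x features log10 matrix (replicate-averaged input expected)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        X = np.log10(table.intensities.T.astype(float))
    return np.where(np.isfinite(X), X, np.nan)


def target_correlates(table: FeatureTable, target: str,
                      r_threshold: float = 0.3, on_log: bool = True):
    """Pearson correlation of every other feature against ``target``.

    Returns ``(positive_ids, negative_ids, frame)`` where the sets contain
    features with |r| >= ``r_threshold`` split by sign, and the frame holds
    per-feature r and the two-sided t-distribution p value.
    """
    ti = table.feature_index(target)
    X = _log_matrix(table) if on_log else table.intensities.T.astype(float)
    y = X[:, ti]
    if np.nanstd(y) == 0:
        raise ValueError(f"target feature {target!r} is constant")
    n_feat = table.n_features
    r = np.full(n_feat, np.nan)
    pval = np.full(n_feat, np.nan)
    for j in range(n_feat):
        if j == ti:
            continue
        ok = np.isfinite(y) & np.isfinite(X[:, j])
        if ok.sum() < 3 or np.std(X[ok, j]) == 0:
            continue
        rj = np.corrcoef(y[ok], X[ok, j])[0, 1]
        r[j] = rj
        df = ok.sum() - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rj * np.sqrt(df / max(1e-300, 1.0 - rj ** 2))
        pval[j] = 2.0 * stats.t.sf(abs(t), df)
    hit = np.abs(r) >= r_threshold
    pos = set(table.feature_id[hit & (r > 0)])
    neg = set(table.feature_id[hit & (r < 0)])
    frame = pd.DataFrame({"feature_id": table.feature_id, "r": r, "p_value": pval})
    frame = frame[frame["feature_id"] != target].reset_index(drop=True)
    logger.info("correlates of %s at |r| >= %g: %d positive, %d negative",
                target, r_threshold, len(pos), len(neg))
    return pos, neg, frame


def adjacency(X: np.ndarray, beta: float = 6.0, mode: str = "unsigned") -> np.ndarray:
    """Soft-threshold adjacency from the sample x feature matrix.

    unsigned: a_ij = |cor|^beta; signed: ((1 + cor)/2)^beta.  The diagonal
    is set to 0 so connectivity sums exclude self-edges.  Constant features
    get zero adjacency (with a warning).
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if mode not in ("unsigned", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        logger.warning("%d constant features excluded from adjacency",
                       int(const.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.where(np.isfinite(C), C, 0.0)
    A = np.abs(C) ** beta if mode == "unsigned" else ((1.0 + C) / 2.0) ** beta
    A[const, :] = 0.0
    A[:, const] = 0.0
    np.fill_diagonal(A, 0.0)
    return A


def topological_overlap(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k_i the connectivity sum; TOM_ii = 1.
    """
    A = np.asarray(A, dtype=float)
    k = A.sum(axis=0)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A) / denom
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------- modules
@dataclass
class ModulePartition:
    """Per-feature module labels (0 = unassigned), ordered by module size."""

    labels: np.ndarray
    n_modules: int
    beta: float
    cut_height: float
    min_size: int

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.labels == module)


def detect_modules(tom: np.ndarray, min_size: int = 10,
                   cut_height: float = 0.99, beta: float = np.nan) -> ModulePartition:
    """Average-linkage hierarchical clustering of the TOM dissimilarity
    (1 - TOM) with a static tree cut at ``cut_height``; clusters smaller
    than ``min_size`` are relabeled 0 and module ids are ordered by
    decreasing size."""
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    linkage = average(squareform(dissim, checks=False))
    raw = fcluster(linkage, t=cut_height, criterion="distance")
    labels = np.zeros(len(raw), dtype=int)
    sizes = pd.Series(raw).value_counts()
    next_id = 1
    for cl, size in sizes.items():
        if size >= min_size:
            labels[raw == cl] = next_id
            next_id += 1
    n_modules = next_id - 1
    if n_modules == 0:
        logger.warning("no module of size >= %d found; all features unassigned",
                       min_size)
    logger.info("detect_modules: %d modules (cut=%g, min_size=%d)",
                n_modules, cut_height, min_size)
    return ModulePartition(labels, n_modules, beta, cut_height, min_size)


def module_eigengene(X_module: np.ndarray):
    """Module eigengene: first principal component of the standardised
    member matrix, as a unit-norm per-sample score vector.

    The sign is oriented so the average correlation with the members is
    nonnegative.  Returns ``(eigengene, variance_explained)``.
    """
    X = np.asarray(X_module, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("module needs >= 2 members")
    sd = X.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("degenerate module: all members constant")
    scale = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=0)) / scale
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    e = U[:, 0]
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    corr = np.array([np.corrcoef(e, Z[:, j])[0, 1] for j in range(Z.shape[1])
                     if Z[:, j].std() > 0])
    if np.nanmean(corr) < 0:
        e = -e
    return e, var_explained


@dataclass
class EigengeneNetwork:
    """Module eigengenes and their adjacency A_IJ = (1 + cor)/2."""

    eigengenes: np.ndarray     # modules x samples
    adjacency: np.ndarray      # modules x modules
    module_ids: np.ndarray
    var_explained: np.ndarray


def eigengene_network(E: np.ndarray, module_ids=None,
                      var_explained=None) -> EigengeneNetwork:
    """Eigengene-network adjacency from a modules x samples eigengene
    matrix: A_IJ = (1 + cor(E_I, E_J)) / 2."""
    E = np.asarray(E, dtype=float)
    if E.shape[0] < 2:
        raise ValueError("need >= 2 modules")
    C = np.corrcoef(E)
    A = (1.0 + C) / 2.0
    A = np.clip((A + A.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(A, 1.0)
    if module_ids is None:
        module_ids = np.arange(1, E.shape[0] + 1)
    if var_explained is None:
        var_explained = np.full(E.shape[0], np.nan)
    return EigengeneNetwork(E, A, np.asarray(module_ids),
                            np.asarray(var_explained))


def _eigengenes_for(X: np.ndarray, partition: ModulePartition) -> EigengeneNetwork:
    E, ve, ids = [], [], []
    for k in range(1, partition.n_modules + 1):
        idx = partition.members(k)
        e, v = module_eigengene(X[:, idx])
        E.append(e); ve.append(v); ids.append(k)
    return eigengene_network(np.stack(E, axis=0), module_ids=np.array(ids),
                             var_explained=np.array(ve))


@dataclass
class PreservationMatrix:
    """Eigengene-network preservation P = 1 - |A_ref - A_test|."""

    P: np.ndarray
    module_ids: np.ndarray
    ref_network: EigengeneNetwork
    test_network: EigengeneNetwork

    def column_means(self, include_diagonal: bool = False) -> np.ndarray:
        """Per-module mean preservation (column means of P; the identically-1
        diagonal is excluded by default)."""
        P = self.P
        if include_diagonal:
            return P.mean(axis=0)
        k = P.shape[0]
        if k == 1:
            return np.array([1.0])
        return (P.sum(axis=0) - np.diag(P)) / (k - 1)


def module_preservation(ref_X: np.ndarray, test_X: np.ndarray,
                        partition: ModulePartition) -> PreservationMatrix:
    """Preservation of the reference modules in a test cohort.

    Eigengenes of the *same* modules are computed in both sample x feature
    matrices (features must align column-wise), both eigengene networks are
    built, and P = 1 - |A_ref - A_test|.
    """
    if ref_X.shape[1] != test_X.shape[1]:
        raise ValueError("reference and test matrices must share features")
    ref_net = _eigengenes_for(ref_X, partition)
    test_net = _eigengenes_for(test_X, partition)
    P = 1.0 - np.abs(ref_net.adjacency - test_net.adjacency)
    np.fill_diagonal(P, 1.0)
    return PreservationMatrix(P, ref_net.module_ids, ref_net, test_net)


# ----------------------------------------------------- model front-end
class CorrelationNetwork:
    """Weighted correlation network model of a (replicate-averaged) cohort.

    statsmodels-style front end: construct from a sample x feature log10
    matrix (or a FeatureTable via :meth:`from_table`), ``fit()`` builds the
    adjacency, TOM, module partition and eigengene network.
    """

    def __init__(self, X: np.ndarray, feature_id=None, beta: float = 6.0,
                 mode: str = "unsigned", min_size: int = 10,
                 cut_height: float = 0.99):
        self.X = np.asarray(X, dtype=float)
        self.feature_id = (np.asarray(feature_id, dtype=object)
                           if feature_id is not None
                           else np.array([f"f{i}" for i in range(self.X.shape[1])],
                                         dtype=object))
        self.beta = beta
        self.mode = mode
        self.min_size = min_size
        self.cut_height = cut_height

    @classmethod
    def from_table(cls, table: FeatureTable, **kwargs) -> "CorrelationNetwork":
        from .qc import average_replicates
        if max(pd.Series(table.sample_ids).value_counts()) > 1:
            table = average_replicates(table)
        X = _log_matrix(table)
        if np.isnan(X).any():
            col_mean = np.nanmean(X, axis=0)
            idx = np.where(np.isnan(X))
            X[idx] = np.take(col_mean, idx[1])
        return cls(X, feature_id=table.feature_id, **kwargs)

    def fit(self) -> "NetworkResults":
        A = adjacency(self.X, beta=self.beta, mode=self.mode)
        tom = topological_overlap(A)
        partition = detect_modules(tom, min_size=self.min_size,
                                   cut_height=self.cut_height, beta=self.beta)
        eig = (_eigengenes_for(self.X, partition)
               if partition.n_modules >= 2 else None)
        return NetworkResults(self, A, tom, partition, eig)


class NetworkResults:
    """Fitted correlation network: adjacency, TOM, modules, eigengenes."""

    def __init__(self, model: CorrelationNetwork, A, tom,
                 partition: ModulePartition, eigengene_net):
        self.model = model
        self.adjacency = A
        self.tom = tom
        self.partition = partition
        self.eigengene_net = eigengene_net

    def module_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature_id": self.model.feature_id,
                             "module": self.partition.labels})

    def preservation(self, test_X: np.ndarray) -> PreservationMatrix:
        return module_preservation(self.model.X, np.asarray(test_X, float),
                                   self.partition)

    def summary(self) -> str:
        sizes = pd.Series(self.partition.labels)
        sizes = sizes[sizes > 0].value_counts().sort_index()
        lines = [
            "Correlation network results",
            "===========================",
            f"{self.model.X.shape[1]} features x {self.model.X.shape[0]} samples; "
            f"beta = {self.model.beta} ({self.model.mode})",
            f"modules: {self.partition.n_modules} "
            f"(cut height {self.model.cut_height}, min size {self.model.min_size}); "
            f"{int((self.partition.labels == 0).sum())} features unassigned",
        ]
        for k, s in sizes.items():
            lines.append(f"  module {k}: {s} features")
        return "\n".join(lines)
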