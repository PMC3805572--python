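"""Multivariate chemometrics: autoscaling, PCA, OSC, PLS-DA, PCLS.

The discriminant workflow is orthogonal signal correction followed by
partial least squares discriminant analysis (OPLS-DA): OSC iteratively
removes components whose scores are orthogonalised against the class
dummies — systematic variation uncorrelated with group membership — and
NIPALS PLS2 then models the corrected matrix against the centred one-hot
group response.  Feature selection (PCLS) ranks features by their multiple
correlation with the first two predictive score vectors, gates candidates
at a correlation threshold and keeps a top fraction by rank; the selection
can be intersected with the FDR-significant set.

The model/results surface follows the statsmodels convention: build an
:class:`OplsDa` from a feature table, call :meth:`~OplsDa.fit`, inspect the
returned :class:`OplsResults` (scores, loadings, explained variation,
``summary()``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable, group_map
from .qc import average_replicates

logger = logging.getLogger("progmet")


# ----------------------------------------------------------------- scaling
@dataclass
class ScaledMatrix:
    """Column-autoscaled matrix with back-transformation metadata."""

    values: np.ndarray  # n_samples x n_features
    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # flags: column had zero variance (centered only)


def autoscale(X: np.ndarray) -> ScaledMatrix:
    """Column-wise centre and unit-variance scale (n-1 SD).  Constant
    columns are centred only and flagged."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("autoscale needs >= 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    scale = np.where(constant, 1.0, sd)
    return ScaledMatrix((X - mean) / scale, mean, sd, constant)


def pca(Z: ScaledMatrix | np.ndarray, k: int):
    """PCA by SVD of the (scaled) matrix.

    Returns ``(scores, loadings, variance_fractions)`` where scores are
    U * S (n x k), loadings are the right singular vectors (p x k) and the
    variance fractions are relative to the total variance.
    """
    X = Z.values if isinstance(Z, ScaledMatrix) else np.asarray(Z, dtype=float)
    n, p = X.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n-1, p)={min(n - 1, p)}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = (s ** 2).sum()
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    varfrac = s[:k] ** 2 / total if total > 0 else np.zeros(k)
    return scores, loadings, varfrac


def group_dummy(labels, groups=None) -> tuple[np.ndarray, list[str]]:
    """Centred one-hot class matrix (one column per group)."""
    labels = np.asarray(labels, dtype=object)
    if groups is None:
        groups = list(dict.fromkeys(labels))
    Y = np.stack([(labels == g).astype(float) for g in groups], axis=1)
    return Y - Y.mean(axis=0), list(groups)


# --------------------------------------------------------------------- OSC
def _orth_against(t: np.ndarray, Y: np.ndarray) -> np.ndarray:
    # t <- t - Y (Y'Y)^-1 Y' t  (least squares handles rank deficiency)
    coef, *_ = np.linalg.lstsq(Y, t, rcond=None)
    return t - Y @ coef


def osc_filter(Z: ScaledMatrix | np.ndarray, Y: np.ndarray, n_osc: int = 1,
               tol: float = 1e-6, max_iter: int = 100):
    """Orthogonal signal correction.

    Per component: seed the score t with the dominant PC of the current
    matrix, orthogonalise t against the (centred) class dummies, find the
    normalised weight vector w minimising ||Xw - t||, recompute t = Xw and
    iterate to convergence; the converged score is orthogonalised a final
    time, the loading p = X't/(t't) is formed and X is deflated by t p'.

    Returns ``(X_corrected, components)`` with one (t, p, w) triple per
    removed component.
    """
    X = (Z.values if isinstance(Z, ScaledMatrix) else np.asarray(Z, float)).copy()
    if n_osc < 1:
        return X, []
    components = []
    for comp in range(n_osc):
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        t = U[:, 0] * s[0]
        Xp = np.linalg.pinv(X)
        for it in range(max_iter):
            t_orth = _orth_against(t, Y)
            w = Xp @ t_orth
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w = w / nw
            t_new = X @ w
            t_new = _orth_against(t_new, Y)
            delta = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
            t = t_new
            if delta < tol:
                break
        else:
            logger.warning("OSC component %d did not converge in %d iterations; "
                           "using best iterate", comp + 1, max_iter)
        tt = float(t @ t)
        if tt == 0:
            break
        p = X.T @ t / tt
        X = X - np.outer(t, p)
        components.append((t, p, w))
    return X, components


# ------------------------------------------------------------------ PLS-DA
@dataclass
class OplsModel:
    """Scores/loadings/weights of an (OSC-)PLS-DA fit."""

    T: np.ndarray            # predictive scores, n x a_p
    P: np.ndarray            # predictive loadings, p x a_p
    W: np.ndarray            # predictive weights, p x a_p
    Q: np.ndarray            # response loadings, g x a_p
    osc_scores: np.ndarray   # n x a_o (may be empty)
    osc_loadings: np.ndarray
    osc_weights: np.ndarray
    y_dummy: np.ndarray      # centred group indicator matrix
    group_names: list = field(default_factory=list)
    sample_ids: np.ndarray | None = None
    labels: np.ndarray | None = None
    r2x: np.ndarray | None = None
    r2y: np.ndarray | None = None


def plsda(Z: ScaledMatrix | np.ndarray, Y: np.ndarray, n_comp: int = 2,
          tol: float = 1e-12, max_iter: int = 500,
          deflate_y: bool = False) -> OplsModel:
    """NIPALS PLS2 against a centred class-dummy response.

    Per component: iterate w ∝ X'u, t = Xw, q ∝ Y't, u = Yq to
    convergence; p = X't/(t't); deflate X (and optionally Y).  Each
    component is sign-oriented so its largest-magnitude loading is
    positive.
    """
    X = (Z.values if isinstance(Z, ScaledMatrix) else np.asarray(Z, float)).copy()
    Yc = np.asarray(Y, dtype=float).copy()
    if Yc.ndim == 1:
        Yc = Yc[:, None]
    n, p_dim = X.shape
    n_comp = min(n_comp, n - 1, p_dim)
    ss_x0 = (X ** 2).sum()
    ss_y0 = (Yc ** 2).sum()
    T, P, W, Q = [], [], [], []
    r2x, r2y = [], []
    Ywork = Yc.copy()
    for comp in range(n_comp):
        u = Ywork[:, np.argmax((Ywork ** 2).sum(axis=0))].copy()
        if np.allclose(u, 0):
            break
        t = np.zeros(n)
        for it in range(max_iter):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t_new = X @ w
            q = Ywork.T @ t_new
            nq = np.linalg.norm(q)
            if nq == 0:
                t = t_new
                break
            q /= nq
            u = Ywork @ q
            delta = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
            t = t_new
            if delta < tol:
                break
        else:
            logger.warning("PLS component %d did not converge in %d iterations; "
                           "using best iterate", comp + 1, max_iter)
        tt = float(t @ t)
        if tt == 0:
            break
        p_load = X.T @ t / tt
        q_load = Yc.T @ t / tt
        # orient: largest-|loading| positive
        j = int(np.argmax(np.abs(p_load)))
        if p_load[j] < 0:
            t, w, p_load, q_load = -t, -w, -p_load, -q_load
        X = X - np.outer(t, p_load)
        if deflate_y:
            Ywork = Ywork - np.outer(t, Ywork.T @ t / tt)
        T.append(t); P.append(p_load); W.append(w); Q.append(q_load)
        r2x.append(tt * (p_load @ p_load) / ss_x0 if ss_x0 > 0 else 0.0)
        r2y.append(tt * (q_load @ q_load) / ss_y0 if ss_y0 > 0 else 0.0)
    a = len(T)
    return OplsModel(
        T=np.stack(T, axis=1) if a else np.empty((n, 0)),
        P=np.stack(P, axis=1) if a else np.empty((p_dim, 0)),
        W=np.stack(W, axis=1) if a else np.empty((p_dim, 0)),
        Q=np.stack(Q, axis=1) if a else np.empty((Yc.shape[1], 0)),
        osc_scores=np.empty((n, 0)),
        osc_loadings=np.empty((p_dim, 0)),
        osc_weights=np.empty((p_dim, 0)),
        y_dummy=Yc,
        r2x=np.asarray(r2x),
        r2y=np.asarray(r2y),
    )


# ------------------------------------------------------- model front-end
def _table_to_matrix(table: FeatureTable, meta: pd.DataFrame, groups,
                     on_log: bool = True):
    """Replicate-averaged log10 sample x feature matrix restricted to the
    requested groups, plus per-sample labels."""
    gm = group_map(meta)
    if max(np.bincount(pd.factorize(table.sample_ids)[0])) > 1:
        table = average_replicates(table)
    labels = np.array([gm.get(s) for s in table.sample_ids], dtype=object)
    keep = np.isin(labels, list(groups))
    table = table.subset_runs(keep)
    labels = labels[keep]
    X = table.intensities.T.astype(float)  # samples x features
    if on_log:
        with np.errstate(divide="ignore", invalid="ignore"):
            X = np.log10(X)
        X = np.where(np.isfinite(X), X, np.nan)
    if np.isnan(X).any():
        # column-mean impute: multivariate stages need a complete matrix
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(col_mean, idx[1])
    return X, labels, table


class OplsDa:
    """OSC-corrected PLS-DA model of group membership from a feature table.

    Parameters
    ----------
    table : FeatureTable
        Intensities (replicates are averaged automatically if present).
    meta : DataFrame
        Sample metadata with ``sample_id`` and ``group``.
    groups : sequence of str
        Two or three group labels to model.
    n_pred, n_osc : int
        Predictive PLS components (default 2) and OSC components removed
        beforehand (default 1; 0 gives plain PLS-DA).
    """

    def __init__(self, table: FeatureTable, meta: pd.DataFrame, groups,
                 n_pred: int = 2, n_osc: int = 1, on_log: bool = True):
        self.groups = list(groups)
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        self.n_pred = n_pred
        self.n_osc = n_osc
        X, labels, sub = _table_to_matrix(table, meta, self.groups, on_log=on_log)
        self.X = X
        self.labels = labels
        self.feature_id = sub.feature_id
        self.sample_ids = sub.sample_ids

    def fit(self, tol: float = 1e-6) -> "OplsResults":
        scaled = autoscale(self.X)
        Y, names = group_dummy(self.labels, self.groups)
        Xc, osc_comps = osc_filter(scaled, Y, n_osc=self.n_osc, tol=tol)
        model = plsda(Xc, Y, n_comp=self.n_pred, deflate_y=False)
        if osc_comps:
            model.osc_scores = np.stack([c[0] for c in osc_comps], axis=1)
            model.osc_loadings = np.stack([c[1] for c in osc_comps], axis=1)
            model.osc_weights = np.stack([c[2] for c in osc_comps], axis=1)
        model.group_names = names
        model.sample_ids = self.sample_ids
        model.labels = self.labels
        return OplsResults(self, model, scaled, Xc)


class OplsResults:
    """Fitted OPLS-DA: scores, loadings, explained variation, diagnostics."""

    def __init__(self, model: OplsDa, fit: OplsModel, scaled: ScaledMatrix,
                 X_corrected: np.ndarray):
        self.model = model
        self.fit_ = fit
        self.scaled = scaled
        self.X_corrected = X_corrected

    @property
    def scores(self) -> np.ndarray:
        return self.fit_.T

    @property
    def loadings(self) -> np.ndarray:
        return self.fit_.P

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.fit_.T,
            columns=[f"t{i + 1}" for i in range(self.fit_.T.shape[1])],
        )
        df.insert(0, "group", self.fit_.labels)
        df.insert(0, "sample_id", self.fit_.sample_ids)
        return df

    def loadings_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.fit_.P,
            columns=[f"p{i + 1}" for i in range(self.fit_.P.shape[1])],
        )
        df.insert(0, "feature_id", self.model.feature_id)
        return df

    def t1_separation(self) -> float:
        """Standardised mean difference of t1 between the first two groups."""
        t1 = self.fit_.T[:, 0]
        g1, g2 = self.model.groups[:2]
        a = t1[self.fit_.labels == g1]
        b = t1[self.fit_.labels == g2]
        pooled = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                         / (len(a) + len(b) - 2))
        return float(abs(a.mean() - b.mean()) / pooled) if pooled > 0 else np.inf

    def summary(self) -> str:
        lines = [
            "OPLS-DA results",
            "===============",
            f"groups: {', '.join(self.model.groups)}   "
            f"n = {len(self.fit_.labels)} samples, "
            f"{len(self.model.feature_id)} features",
            f"components: {self.fit_.T.shape[1]} predictive, "
            f"{self.fit_.osc_scores.shape[1]} orthogonal (OSC)",
        ]
        for i, (rx, ry) in enumerate(zip(self.fit_.r2x, self.fit_.r2y)):
            lines.append(f"  t{i + 1}: R2X = {rx:.4f}   R2Y = {ry:.4f}")
        lines.append(f"t1 group separation (SMD): {self.t1_separation():.3f}")
        return "\n".join(lines)


def oplsda(table: FeatureTable, meta: pd.DataFrame, groups,
           n_pred: int = 2, n_osc: int = 1, on_log: bool = True) -> OplsResults:
    """Convenience wrapper: fit an :class:`OplsDa` model in one call."""
    return OplsDa(table, meta, groups, n_pred=n_pred, n_osc=n_osc,
                  on_log=on_log).fit()


# -------------------------------------------------------------------- PCLS
@dataclass
class PclsResult:
    """Per-feature PCLS statistics and selections."""

    table: pd.DataFrame       # feature_id, r_t1, r_t2, combined_R, candidate,
                              # selected, rank
    corr_threshold: float
    top_fraction: float
    rank_by: str

    @property
    def selected_ids(self) -> set:
        return set(self.table.loc[self.table["selected"], "feature_id"])

    @property
    def candidate_ids(self) -> set:
        return set(self.table.loc[self.table["candidate"], "feature_id"])


def pcls_select(results: OplsResults, corr_threshold: float = 0.95,
                top_fraction: float = 0.05, rank_by: str = "combined_R",
                selection_within: str = "all") -> PclsResult:
    """PCLS feature selection from a fitted OPLS-DA.

    Per feature the combined correlation R is the multiple correlation of
    the (autoscaled) feature column on the first two predictive score
    vectors.  Two flags are reported: *candidate* (R >= ``corr_threshold``)
    and *selected* (the top ``round(top_fraction * m)`` features ranked by
    ``combined_R`` or ``loading_magnitude``).  With
    ``selection_within="all"`` (default) the ranking and the count run
    over the full feature set, so the selection stays meaningful when no
    feature reaches the absolute correlation gate; with ``"candidates"``
    both are restricted to the gated set (selected is then a subset of
    candidate).
    """
    fit = results.fit_
    if fit.T.shape[1] < 2:
        raise ValueError("PCLS needs >= 2 predictive components")
    if rank_by not in ("combined_R", "loading_magnitude"):
        raise ValueError(f"unknown rank_by {rank_by!r}")
    Z = results.scaled.values
    T2 = fit.T[:, :2]
    # multiple correlation: ||proj of z onto span(t1,t2)|| / ||z||
    Qmat, _ = np.linalg.qr(T2 - T2.mean(axis=0))
    Zc = Z - Z.mean(axis=0)
    norms = np.linalg.norm(Zc, axis=0)
    norms = np.where(norms == 0, np.inf, norms)
    proj = Qmat.T @ Zc
    R = np.sqrt((proj ** 2).sum(axis=0)) / norms
    r1 = (fit.T[:, 0] - fit.T[:, 0].mean()) @ Zc / (
        np.linalg.norm(fit.T[:, 0] - fit.T[:, 0].mean()) * norms
    )
    r2 = (fit.T[:, 1] - fit.T[:, 1].mean()) @ Zc / (
        np.linalg.norm(fit.T[:, 1] - fit.T[:, 1].mean()) * norms
    )
    if selection_within not in ("all", "candidates"):
        raise ValueError(f"unknown selection_within {selection_within!r}")
    candidate = R >= corr_threshold
    key = R if rank_by == "combined_R" else np.abs(fit.P[:, 0])
    order = np.argsort(-key, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    selected = np.zeros(len(R), dtype=bool)
    if selection_within == "all":
        n_select = int(round(top_fraction * len(R)))
        selected[order[:n_select]] = True
    else:
        n_select = int(round(top_fraction * int(candidate.sum())))
        cand_order = [i for i in order if candidate[i]]
        for i in cand_order[:n_select]:
            selected[i] = True
    df = pd.DataFrame(
        {
            "feature_id": results.model.feature_id,
            "r_t1": r1,
            "r_t2": r2,
            "combined_R": R,
            "candidate": candidate,
            "selected": selected,
            "rank": rank,
        }
    )
    logger.info("PCLS: %d candidates (R >= %g), %d selected (top %g)",
                int(candidate.sum()), corr_threshold, int(selected.sum()),
                top_fraction)
    return PclsResult(df, corr_threshold, top_fraction, rank_by)


def intersect_selections(set_a, set_b):
    """Exact intersection with Venn counts (a-only, b-only, both)."""
    a, b = set(set_a), set(set_b)
    both = a & b
    venn = {"a_only": len(a - b), "b_only": len(b - a), "both": len(both)}
    logger.info("selection overlap: %(a_only)d a-only, %(b_only)d b-only, "
                "%(both)d shared", venn)
    return both, venn
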