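"""Latent-variable models: PCA and two-class PLS-DA with VIP.

Both models follow the model/results split: construct the model from a
preprocessed (centered, optionally scaled) matrix, call :meth:`fit`, and
read estimates off the returned results object.

PCA is computed by singular value decomposition; PLS-DA by NIPALS PLS2
on a centered one-hot class indicator, the reference algorithm in
chemometrics.  Component signs are fixed so that the largest-magnitude
loading entry of each component is positive, making runs reproducible.

Variable importance in projection (VIP) summarizes each variable's
contribution to the class separation across components:

    VIP_j = sqrt( p * sum_a [ SSY_a * (w_ja / ||w_a||)^2 ] / sum_a SSY_a )

with p variables and SSY_a the response variance explained by component
a; by construction mean(VIP^2) = 1, so VIP >= 1 flags variables that
carry more than an average share of the discrimination.

:func:`multilevel_split` separates a repeated-measures table into
within-subject deviations and between-subject means, the multilevel
decomposition for paired designs: latent fits on the within part answer
"how does each subject move over time", free of subject-level offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MetaboliteProfileTable, UrometError, ValidationError


class RankError(UrometError):
    """Requested more components than the matrix rank supports."""


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X,
                        index=[f"s{i}" for i in range(X.shape[0])],
                        columns=[f"v{j}" for j in range(X.shape[1])])


def _fix_signs(loadings: np.ndarray, *others: np.ndarray) -> None:
    """Flip column signs in place so the largest-|entry| loading per
    component is positive (first occurrence on ties)."""
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            for o in others:
                o[:, a] *= -1


@dataclass
class PCAResults:
    """Fitted PCA: orthonormal loadings, scores = X @ loadings, and
    per-component explained-variance fractions (summing to 1 over the
    full rank)."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: pd.Series
    singular_values: np.ndarray
    n_components: int
    kind: str = "pca"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "explained_fraction": self.explained,
            "cumulative": self.explained.cumsum(),
        })


class PCA:
    """Principal component analysis of a column-centered matrix.

    Parameters
    ----------
    X :
        Samples x variables matrix, already column-centered (the
        preprocessing stage centers; PCA does not re-center).
    n_components :
        Number of components to retain; must not exceed the matrix rank.
    """

    def __init__(self, X, n_components: int = 2):
        self.X = _as_frame(X)
        self.n_components = int(n_components)

    def fit(self) -> PCAResults:
        X = self.X.to_numpy(dtype=float)
        n, p = X.shape
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        tol = max(n, p) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        rank = int((s > tol).sum())
        k = self.n_components
        if k > rank:
            raise RankError(
                f"requested {k} components but the matrix rank is {rank}")
        loadings = Vt.T[:, :k].copy()
        scores = X @ loadings
        _fix_signs(loadings, scores)
        total = float((s ** 2).sum())
        explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
        comp = [f"PC{a + 1}" for a in range(k)]
        return PCAResults(
            scores=pd.DataFrame(scores, index=self.X.index, columns=comp),
            loadings=pd.DataFrame(loadings, index=self.X.columns, columns=comp),
            explained=pd.Series(explained, index=comp),
            singular_values=s[:k].copy(),
            n_components=k,
        )


def pca_padded(X, n_components: int) -> PCAResults:
    """PCA that tolerates rank-deficient input by padding with zero
    components, for derived analyses whose component count is set by the
    design (factor levels, plot dimensions) rather than the data rank."""
    X = _as_frame(X)
    s = np.linalg.svd(X.to_numpy(dtype=float), compute_uv=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    comp = [f"PC{a + 1}" for a in range(n_components)]
    if rank == 0:
        return PCAResults(
            scores=pd.DataFrame(0.0, index=X.index, columns=comp),
            loadings=pd.DataFrame(0.0, index=X.columns, columns=comp),
            explained=pd.Series(0.0, index=comp),
            singular_values=np.zeros(n_components),
            n_components=n_components)
    model = PCA(X, min(n_components, rank)).fit()
    for a in range(model.n_components, n_components):
        c = f"PC{a + 1}"
        model.scores[c] = 0.0
        model.loadings[c] = 0.0
        model.explained[c] = 0.0
    model.singular_values = np.concatenate(
        [model.singular_values, np.zeros(n_components - model.n_components)])
    model.n_components = n_components
    return model


@dataclass
class PLSDAResults:
    """Fitted two-class PLS-DA (NIPALS PLS2 on a centered indicator).

    ``explained_y`` holds SSY_a, the fraction of response variance
    captured by each component; ``vip`` the variable importances.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    weights: pd.DataFrame
    y_loadings: np.ndarray
    explained_x: pd.Series
    explained_y: pd.Series
    vip: pd.Series
    class_labels: pd.Series
    n_components: int
    kind: str = "plsda"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "explained_x": self.explained_x,
            "explained_y": self.explained_y,
            "cumulative_y": self.explained_y.cumsum(),
        })


class PLSDA:
    """Two-class partial least squares discriminant analysis.

    ``y`` must contain exactly two classes with at least two samples
    each.  The response is the centered one-hot class indicator; the
    model is fitted with NIPALS PLS2.
    """

    def __init__(self, X, y, n_components: int = 2, max_iter: int = 500,
                 tol: float = 1e-10):
        self.X = _as_frame(X)
        self.y = pd.Series(np.asarray(y), index=self.X.index)
        self.n_components = int(n_components)
        self.max_iter = max_iter
        self.tol = tol

    def fit(self) -> PLSDAResults:
        classes, counts = np.unique(self.y.to_numpy(), return_counts=True)
        if len(classes) != 2:
            raise ValidationError(
                f"PLS-DA needs exactly two classes, got {len(classes)}")
        if counts.min() < 2:
            raise ValidationError("each class needs at least 2 samples")
        X = self.X.to_numpy(dtype=float)
        n, p = X.shape
        Y = np.zeros((n, 2))
        for c, cls in enumerate(classes):
            Y[self.y.to_numpy() == cls, c] = 1.0
        Y = Y - Y.mean(axis=0)

        rank = np.linalg.matrix_rank(X)
        k = self.n_components
        if k > rank:
            raise RankError(
                f"requested {k} components but the matrix rank is {rank}")

        ssx_tot = float((X ** 2).sum())
        ssy_tot = float((Y ** 2).sum())
        E, F = X.copy(), Y.copy()
        W = np.zeros((p, k))
        T = np.zeros((n, k))
        P = np.zeros((p, k))
        Q = np.zeros((2, k))
        ssx = np.zeros(k)
        ssy = np.zeros(k)
        for a in range(k):
            u = F[:, int(np.argmax((F ** 2).sum(axis=0)))].copy()
            t_old = None
            w = t = None
            for _ in range(self.max_iter):
                w = E.T @ u
                nw = np.linalg.norm(w)
                if nw == 0:
                    w = None
                    break
                w /= nw
                t = E @ w
                q = F.T @ t / float(t @ t)
                denom = float(q @ q)
                if denom == 0:
                    break
                u = F @ q / denom
                if t_old is not None and np.linalg.norm(t - t_old) <= self.tol * np.linalg.norm(t):
                    break
                t_old = t
            if w is None or t is None or float(t @ t) == 0.0:
                break  # no class-correlated variation left: zero component
            pa = E.T @ t / float(t @ t)
            E = E - np.outer(t, pa)
            F = F - np.outer(t, q)
            W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, pa, q
            ssx[a] = float(t @ t) * float(pa @ pa) / ssx_tot if ssx_tot else 0.0
            ssy[a] = float(t @ t) * float(q @ q) / ssy_tot if ssy_tot else 0.0

        _fix_signs(P, W, T, Q)

        comp = [f"LV{a + 1}" for a in range(k)]
        weights = pd.DataFrame(W, index=self.X.columns, columns=comp)
        res = PLSDAResults(
            scores=pd.DataFrame(T, index=self.X.index, columns=comp),
            loadings=pd.DataFrame(P, index=self.X.columns, columns=comp),
            weights=weights,
            y_loadings=Q,
            explained_x=pd.Series(ssx, index=comp),
            explained_y=pd.Series(ssy, index=comp),
            vip=pd.Series(np.nan, index=self.X.columns),
            class_labels=self.y.copy(),
            n_components=k,
        )
        try:
            res.vip = compute_vip(res)
        except ValidationError:
            pass  # degenerate model (no class signal): VIP stays NaN
        return res


def compute_vip(model: PLSDAResults) -> pd.Series:
    """Variable importance in projection for a fitted PLS-DA model.

    Weight-based definition (see module docstring); normalized so that
    the mean squared VIP over variables is 1.
    """
    if model.kind != "plsda":
        raise ValidationError("VIP is defined for PLS-DA models only")
    W = model.weights.to_numpy(dtype=float)
    p, k = W.shape
    ssy = model.explained_y.to_numpy(dtype=float)
    total = ssy.sum()
    if total <= 0:
        raise ValidationError(
            "degenerate PLS-DA model: zero explained response variance")
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    Wn = W / norms
    vip = np.sqrt(p * (Wn ** 2 @ ssy) / total)
    return pd.Series(vip, index=model.weights.index, name="VIP")


def multilevel_split(table: MetaboliteProfileTable, scope: str = "within"
                     ) -> pd.DataFrame:
    """Multilevel (within/between subject) split of a repeated-measures
    table's value matrix.

    ``within`` returns each experimental sample's deviation from its
    subject's mean profile (indexed by sample_id); ``between`` returns
    one row per subject holding the subject mean profile.  Adding the
    subject-mean broadcast back to the within part reconstructs the
    original matrix exactly.
    """
    if scope not in ("within", "between"):
        raise ValidationError(f"unknown scope {scope!r}")
    exp = table.experimental
    counts = exp.groupby("subject_id").size()
    lonely = counts.index[counts < 2].tolist()
    if lonely:
        raise ValidationError(
            f"subject(s) with a single sample: {', '.join(map(str, lonely))}")
    vals = exp[table.metabolites].astype(float)
    vals.index = exp["sample_id"]
    subj = exp["subject_id"].to_numpy()
    means = vals.groupby(subj).transform("mean")
    if scope == "within":
        return vals - means
    between = vals.groupby(subj).mean()
    between.index.name = "subject_id"
    return between
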