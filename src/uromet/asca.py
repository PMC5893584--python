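"""ANOVA-simultaneous component analysis (ASCA).

ASCA partitions a column-centered data matrix by the levels of the
design factors, exactly as a main-effects ANOVA does per variable, and
then summarizes each factor's effect matrix by component analysis:

    X = sum_F  M_F  +  E

where the effect matrix M_F assigns each sample the mean profile of its
level of factor F (grand mean removed) and E is the residual.  For a
balanced crossed design the effect matrices are mutually orthogonal and
the sums of squares add up to the total, so the per-factor SSQ fractions
read like an ANOVA table across all variables at once.

Simultaneous component analysis (SCA) of a factor's effect matrix is a
PCA of that matrix; its scores place the factor levels in a low-
dimensional space (optionally with the residual projected onto the
effect loadings, so individual samples scatter around their level
centroid).  Significance of a factor is assessed by a permutation test
that permutes the tested factor's labels within the levels of the other
factors, respecting the nesting of time within subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._ellipse import confidence_ellipse
from .datamodel import ValidationError
from .latent import PCAResults, RankError, _as_frame, pca_padded


def _factor_frame(factors, index) -> pd.DataFrame:
    f = pd.DataFrame(factors)
    if len(f) != len(index):
        raise ValidationError("factor frame length does not match X")
    f.index = index
    return f


def _effect_matrix(Xc: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Level-mean matrix: each row gets the mean profile of its level."""
    g = Xc.groupby(labels, sort=False).transform("mean")
    return g


@dataclass
class ASCAResults:
    """Additive decomposition of a centered matrix by design factors."""

    grand_mean: pd.Series
    effects: dict[str, pd.DataFrame]
    residual: pd.DataFrame
    factor_ssq: dict[str, float]
    residual_ssq: float
    total_ssq: float
    balanced: bool
    factors: pd.DataFrame
    X: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        rows = [{"factor": f, "ssq": s,
                 "fraction": s / self.total_ssq if self.total_ssq else 0.0}
                for f, s in self.factor_ssq.items()]
        rows.append({"factor": "residual", "ssq": self.residual_ssq,
                     "fraction": (self.residual_ssq / self.total_ssq
                                  if self.total_ssq else 0.0)})
        return pd.DataFrame(rows)

    def sca(self, factor: str, n_components: int = 2, *,
            augment_residual: bool = False, ellipse_level: float = 0.95
            ) -> tuple[PCAResults, pd.DataFrame]:
        """Simultaneous component analysis of one factor's effect matrix.

        Returns the PCA of the effect matrix and a per-level frame with
        centroids and confidence-ellipse parameters on the first two
        components.  With ``augment_residual`` the residual is projected
        onto the effect loadings and added to the scores, so each
        sample scatters around its level centroid; without it all
        samples of a level coincide with the centroid.
        """
        if factor not in self.effects:
            raise ValidationError(f"unknown factor {factor!r}")
        M = self.effects[factor]
        levels = self.factors[factor]
        n_levels = levels.nunique()
        if n_components > n_levels - 1:
            raise RankError(
                f"factor {factor!r} has {n_levels} levels, so its effect "
                f"matrix has rank <= {n_levels - 1}; requested "
                f"{n_components} components")
        # the bound above is the design bound (levels - 1); degenerate data
        # can leave the effect matrix with even lower rank, which is padded
        model = pca_padded(M, n_components)
        scores = model.scores.copy()
        if augment_residual:
            scores = scores + self.residual.to_numpy() @ model.loadings.to_numpy()
        rows = []
        for lev, grp in scores.groupby(levels.to_numpy(), sort=True):
            pts = grp.iloc[:, :2].to_numpy()
            ell = confidence_ellipse(pts, level=ellipse_level, scope="centroid")
            row = {"level": lev}
            row.update({c: float(grp[c].mean()) for c in scores.columns})
            row.update({"ellipse_a": ell["a"], "ellipse_b": ell["b"],
                        "ellipse_angle": ell["angle_deg"]})
            rows.append(row)
        model.scores = scores
        return model, pd.DataFrame(rows)


class ASCA:
    """ASCA model of a centered matrix with categorical design factors.

    Parameters
    ----------
    X :
        Samples x variables matrix, column-centered (preprocessed).
    factors :
        Mapping or DataFrame of per-sample factor labels, e.g.
        ``{"time": ..., "subject": ...}``.  Main effects only.
    """

    def __init__(self, X, factors):
        self.X = _as_frame(X)
        self.factors = _factor_frame(factors, self.X.index)

    def fit(self) -> ASCAResults:
        grand = self.X.mean(axis=0)
        Xc = self.X - grand
        effects: dict[str, pd.DataFrame] = {}
        for f in self.factors.columns:
            labels = self.factors[f].to_numpy()
            lev, counts = np.unique(labels, return_counts=True)
            if counts.min() == 0:  # pragma: no cover - unique can't return 0
                raise ValidationError(f"factor {f!r} has an empty level")
            effects[f] = _effect_matrix(Xc, labels)
        residual = Xc - sum(effects.values())
        sizes = self.factors.groupby(list(self.factors.columns)).size()
        n_cells = int(np.prod([self.factors[c].nunique()
                               for c in self.factors.columns]))
        balanced = sizes.nunique() == 1 and len(sizes) == n_cells
        ssq = {f: float((m.to_numpy() ** 2).sum()) for f, m in effects.items()}
        return ASCAResults(
            grand_mean=grand,
            effects=effects,
            residual=residual,
            factor_ssq=ssq,
            residual_ssq=float((residual.to_numpy() ** 2).sum()),
            total_ssq=float((Xc.to_numpy() ** 2).sum()),
            balanced=bool(balanced),
            factors=self.factors,
            X=Xc,
        )


def asca_permutation_test(X, factors, factor: str, n_perm: int = 199,
                          seed: int | None = None) -> dict:
    """Permutation p-value for one factor's effect in an ASCA model.

    The test statistic is the factor's effect sum of squares.  The null
    is built by permuting the tested factor's labels within the levels
    of the other factors (e.g. time permuted within subject), which
    respects the repeated-measures structure, and
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be at least 99")
    X = _as_frame(X)
    factors = _factor_frame(factors, X.index)
    if factor not in factors.columns:
        raise ValidationError(f"unknown factor {factor!r}")
    rng = np.random.default_rng(seed)

    Xc = (X - X.mean(axis=0)).to_numpy()
    others = [c for c in factors.columns if c != factor]
    if others:
        groups = factors[others].astype(str).agg("|".join, axis=1).to_numpy()
    else:
        groups = np.zeros(len(X), dtype=int)
    labels = factors[factor].to_numpy()

    def stat(lab: np.ndarray) -> float:
        df = pd.DataFrame(Xc)
        m = df.groupby(lab, sort=False).transform("mean").to_numpy()
        return float((m ** 2).sum())

    observed = stat(labels)
    exceed = 0
    perm = labels.copy()
    group_idx = [np.flatnonzero(groups == g) for g in np.unique(groups)]
    for _ in range(n_perm):
        for idx in group_idx:
            perm[idx] = labels[idx][rng.permutation(len(idx))]
        if stat(perm) >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return {"factor": factor, "statistic": observed, "n_perm": n_perm,
            "p_value": p}
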