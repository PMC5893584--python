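"""Unfolded-tensor PCA with per-case trajectories and bi-plot ranking.

A longitudinal profiling study is a three-way array: cases x metabolites
x sampling hours.  Batch-wise unfolding rearranges it into a two-way
matrix with one row per case and one column per (metabolite, hour)
pair, so ordinary PCA can treat each case's whole time course as a
single profile and thereby account for the repeated measures.

After fitting PCA to the unfolded matrix, the score of a case splits
additively over the time blocks: the "block score" of case i at hour t
is the product of its hour-t sub-profile with the hour-t block of the
loadings, and the block scores of a case sum to its total score (the
matrix is column-centered, so no offset remains).  Plotting the block
scores in hour order traces a trajectory per case; their per-hour means
are the time centroids, with confidence ellipses describing the spread
of cases at each hour.

Metabolites are ranked for bi-plots by the sum of squared loadings on
the first two components, optionally restricted to one hour's block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._ellipse import confidence_ellipse
from .datamodel import MetaboliteProfileTable, UrometError, ValidationError
from .latent import PCAResults, pca_padded


@dataclass
class UnfoldedMatrix:
    """Cases x (metabolite, hour) matrix from batch-wise unfolding.

    ``values`` has a two-level column MultiIndex (metabolite, time_h) in
    fixed lexicographic order; ``block_index`` maps each hour to the
    positional columns of its block.
    """

    values: pd.DataFrame

    @property
    def cases(self) -> list:
        return list(self.values.index)

    @property
    def metabolites(self) -> list[str]:
        return sorted(set(self.values.columns.get_level_values(0)))

    @property
    def times(self) -> list[int]:
        return sorted(set(self.values.columns.get_level_values(1)))

    @property
    def block_index(self) -> dict[int, np.ndarray]:
        t_level = self.values.columns.get_level_values(1)
        return {t: np.flatnonzero(t_level == t) for t in self.times}


def unfold(table: MetaboliteProfileTable, intervention: str | None = "alcohol",
           mode: str = "cases") -> UnfoldedMatrix | pd.DataFrame:
    """Unfold one intervention arm into a cases x (metabolite, hour) matrix.

    Each case is a subject (within the chosen arm); with
    ``intervention=None`` both arms are unfolded jointly and a case is a
    ``subject|arm`` pair.  Every case must have a complete time series;
    a missing (case, hour) cell raises an error naming the gap.

    ``mode='observations'`` returns the alternative observation-rows
    layout instead: a plain frame with one row per (case, hour) and one
    column per metabolite (each repeated measure its own row, as in the
    original table).
    """
    if mode not in ("cases", "observations"):
        raise ValidationError(f"unknown unfolding mode {mode!r}")
    exp = table.experimental
    if intervention is not None:
        exp = exp[exp["intervention"] == intervention]
        if exp.empty:
            raise ValidationError(f"no experimental samples in arm {intervention!r}")
        case = exp["subject_id"].astype(str)
    else:
        case = exp["subject_id"].astype(str) + "|" + exp["intervention"].astype(str)
    metab = table.metabolites
    times = sorted(exp["time_h"].unique())
    long = exp[metab].copy()
    long["_case"] = case.to_numpy()
    long["_time"] = exp["time_h"].to_numpy()
    for c in sorted(case.unique()):
        have = set(long.loc[long["_case"] == c, "_time"])
        gap = [t for t in times if t not in have]
        if gap:
            raise ValidationError(
                f"case {c!r}: missing sample at hour(s) {gap}")
    wide = long.set_index(["_case", "_time"])[metab].unstack("_time")
    # columns now (metabolite, time); fix lexicographic order
    wide = wide.sort_index(axis=1)
    wide.columns = wide.columns.set_names(["metabolite", "time_h"])
    wide.index.name = "case"
    U = UnfoldedMatrix(values=wide)
    if mode == "observations":
        return refold(U)
    return U


def refold(U: UnfoldedMatrix) -> pd.DataFrame:
    """Inverse of :func:`unfold`: long frame indexed by (case, time_h)
    with one metabolite per column."""
    out = U.values.stack("time_h", future_stack=True)
    out = out[U.metabolites]
    return out.sort_index()


@dataclass
class UnfoldedPCAResults:
    """PCA of the unfolded matrix plus time-resolved derivations."""

    model: PCAResults
    block_scores: pd.DataFrame  # (case, time_h) x components
    trajectories: pd.DataFrame  # long: case, time_h, PC1, PC2
    centroids: pd.DataFrame     # time_h, PC1, PC2, ellipse params
    column_means: pd.Series

    def summary(self) -> pd.DataFrame:
        return self.model.summary()


class UnfoldedPCA:
    """PCA of a batch-wise unfolded matrix with per-hour block scores.

    The matrix is column-centered before fitting (means retained).
    ``ellipse_level`` sets the per-hour confidence ellipse of the case
    scores (0.90 by default for trajectory plots).
    """

    def __init__(self, U: UnfoldedMatrix, n_components: int = 2,
                 ellipse_level: float = 0.90):
        self.U = U
        self.n_components = int(n_components)
        self.ellipse_level = float(ellipse_level)

    def fit(self) -> UnfoldedPCAResults:
        vals = self.U.values
        means = vals.mean(axis=0)
        Xc = vals - means
        model = pca_padded(Xc, self.n_components)
        L = model.loadings.to_numpy()
        comp = list(model.scores.columns)
        blocks = []
        for t, idx in self.U.block_index.items():
            bs = Xc.iloc[:, idx].to_numpy() @ L[idx, :]
            df = pd.DataFrame(bs, index=vals.index, columns=comp)
            df.insert(0, "time_h", t)
            blocks.append(df)
        block_scores = (pd.concat(blocks)
                        .set_index("time_h", append=True)
                        .sort_index())
        traj = block_scores.reset_index().sort_values(["case", "time_h"])
        cent_rows = []
        for t in self.U.times:
            pts = block_scores.xs(t, level="time_h")[comp[:2]].to_numpy()
            if pts.shape[1] == 1:  # 1-component fit: ellipse in (PC1, 0)
                pts = np.column_stack([pts, np.zeros(len(pts))])
            ell = confidence_ellipse(pts, level=self.ellipse_level,
                                     scope="scores")
            row = {"time_h": t}
            row.update({c: float(block_scores.xs(t, level="time_h")[c].mean())
                        for c in comp})
            row.update({"ellipse_a": ell["a"], "ellipse_b": ell["b"],
                        "ellipse_angle": ell["angle_deg"]})
            cent_rows.append(row)
        return UnfoldedPCAResults(
            model=model,
            block_scores=block_scores,
            trajectories=traj,
            centroids=pd.DataFrame(cent_rows),
            column_means=means,
        )


def biplot_rank(model: PCAResults, top_k: int = 7,
                time_h: int | None = None) -> pd.DataFrame:
    """Rank metabolites by squared loadings on the first two components.

    For a model fitted to an unfolded matrix the loadings index is a
    (metabolite, time_h) MultiIndex; ``time_h`` restricts the ranking to
    one hour's block (the time-resolved bi-plots), otherwise squared
    loadings are summed over all hours per metabolite.  Ties are broken
    lexicographically by metabolite name.

    Returns a frame with columns metabolite, rank, ss_loadings, l1, l2.
    """
    if model.loadings.shape[1] < 2:
        raise ValidationError("bi-plot ranking needs at least 2 components")
    load = model.loadings.iloc[:, :2]
    if isinstance(load.index, pd.MultiIndex):
        if time_h is not None:
            load = load.xs(time_h, level=1)
            ss = load.iloc[:, 0] ** 2 + load.iloc[:, 1] ** 2
        else:
            ss = (load ** 2).sum(axis=1).groupby(level=0).sum()
            load = load.groupby(level=0).sum()
    elif time_h is not None:
        raise ValidationError("loadings carry no time level to restrict to")
    else:
        ss = load.iloc[:, 0] ** 2 + load.iloc[:, 1] ** 2
    l1, l2 = load.iloc[:, 0], load.iloc[:, 1]
    out = pd.DataFrame({
        "metabolite": load.index.astype(str),
        "ss_loadings": ss.to_numpy(),
        "l1": l1.to_numpy(),
        "l2": l2.to_numpy(),
    })
    out = out.sort_values(["ss_loadings", "metabolite"],
                          ascending=[False, True], kind="mergesort")
    out.insert(1, "rank", np.arange(1, len(out) + 1))
    if top_k > len(out):
        warnings.warn(
            f"top_k={top_k} exceeds metabolite count {len(out)}; truncated",
            stacklevel=2)
        top_k = len(out)
    return out.head(top_k).reset_index(drop=True)
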