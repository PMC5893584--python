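"""Preprocessing: creatinine normalization, zero treatment, log transform
and scaling, and QC/repeat-injection diagnostics.

The canonical preprocessing chain for a raw table is::

    table = normalize_to_creatinine(table)   # umol/L -> umol/mmol Cr
    table = impute_zeros(table)              # half-minimum rule
    table = transform_scale(table, "auto")   # ln, center, unit variance

Zero treatment uses the half-minimum convention: a non-detect (exact
zero) is replaced by half the smallest positive value of that metabolite
over the experimental samples, which keeps the subsequent log transform
defined without distorting the detected range.  Metabolites that are
zero in every experimental sample carry no information and are dropped
with a warning.

QC rows (pooled-urine injections) and repeat injections never enter
statistical fits; :func:`qc_repeatability` summarizes them as per-batch
relative standard deviations and repeat/original percent differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    MetaboliteProfileTable,
    NormalizationError,
    ValidationError,
)


@dataclass
class ScalerParams:
    """Per-column transform parameters retained for projecting held-out
    rows onto a fitted model's preprocessing.

    Columns are transformed as ``(ln(v) - mean) / scale`` where ``scale``
    depends on the scaling mode: ``auto`` uses the column standard
    deviation (unit variance), ``pareto`` its square root, ``none`` uses 1
    (centering only).  Parameters are estimated on experimental rows only.
    """

    mean: pd.Series
    sd: pd.Series
    scaling: str
    zero_variance: list[str] = field(default_factory=list)

    @property
    def scale(self) -> pd.Series:
        if self.scaling == "auto":
            s = self.sd.copy()
        elif self.scaling == "pareto":
            s = np.sqrt(self.sd)
        elif self.scaling == "none":
            s = pd.Series(1.0, index=self.sd.index)
        else:  # pragma: no cover
            raise ValueError(f"unknown scaling {self.scaling!r}")
        s[s == 0] = 1.0  # flagged columns: center only
        return s

    def project(self, values: pd.DataFrame, *, already_log: bool = False) -> pd.DataFrame:
        """Apply the retained log/center/scale transform to new rows."""
        v = values[self.mean.index]
        if not already_log:
            v = np.log(v)
        return (v - self.mean) / self.scale


def normalize_to_creatinine(table: MetaboliteProfileTable) -> MetaboliteProfileTable:
    """Express concentrations relative to urinary creatinine.

    Each value v (umol/L) becomes v / creatinine (mmol/L), i.e.
    umol metabolite / mmol Cr, correcting for between-void differences in
    urine dilution (water consumption).  Every row — experimental, QC or
    repeat — is normalized by its own creatinine.
    """
    if table.normalized:
        raise NormalizationError("table is already creatinine-normalized")
    cr = pd.to_numeric(table.data["creatinine_mmol_per_L"], errors="coerce")
    bad = cr.isna() | (cr <= 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise NormalizationError(
            f"sample {table.data['sample_id'].iat[i]!r}: creatinine must be "
            f"> 0 mmol/L (got {table.data['creatinine_mmol_per_L'].iat[i]!r})")
    vals = table.values.div(cr, axis=0)
    return table.replace_values(vals, normalized=True)


def impute_zeros(table: MetaboliteProfileTable) -> MetaboliteProfileTable:
    """Half-minimum treatment of zero-valued observations.

    Exact zeros become half the minimum positive value of that metabolite
    across experimental samples.  All-zero metabolites are dropped and
    listed in ``table.dropped_metabolites`` (with a warning), mirroring a
    mechanical variable-reduction step.
    """
    if table.transform_state != "raw":
        raise ValidationError(
            f"impute_zeros expects a raw table, got {table.transform_state!r}")
    exp = table.experimental[table.metabolites]
    minpos = exp.where(exp > 0).min()
    all_zero = minpos.index[minpos.isna()].tolist()
    vals = table.values.copy()
    if all_zero:
        warnings.warn(
            f"dropping {len(all_zero)} all-zero metabolite(s): "
            f"{', '.join(all_zero)}", stacklevel=2)
        vals = vals.drop(columns=all_zero)
        minpos = minpos.drop(all_zero)
    fill = minpos / 2.0
    for col in vals.columns[(vals == 0).any()]:
        vals.loc[vals[col] == 0, col] = fill[col]
    out = table.replace_values(vals, transform_state="imputed")
    out.dropped_metabolites = table.dropped_metabolites + all_zero
    return out


def transform_scale(table: MetaboliteProfileTable,
                    scaling: str = "auto") -> MetaboliteProfileTable:
    """Natural-log transform, then column-wise centering and scaling.

    ``auto`` divides by the column standard deviation (unit variance,
    making VIP comparable across concentration scales), ``pareto`` by its
    square root, ``none`` centers only.  Parameters are estimated on
    experimental rows and retained in ``table.scaler`` so held-out rows
    (e.g. QC injections) can be projected identically.  Zero-variance
    columns under auto scaling are centered only and flagged in
    ``scaler.zero_variance`` for exclusion from latent fits.
    """
    if scaling not in ("auto", "pareto", "none"):
        raise ValidationError(f"unknown scaling {scaling!r}")
    if table.transform_state != "imputed":
        raise ValidationError(
            f"transform_scale expects an imputed table, got "
            f"{table.transform_state!r}")
    vals = table.values
    if (vals.to_numpy() <= 0).any():
        raise ValidationError("all values must be > 0 before log transform")
    logged = np.log(vals)
    exp_mask = (table.data["role"] == "experimental").to_numpy()
    mean = logged[exp_mask].mean()
    sd = logged[exp_mask].std(ddof=1)
    zero_var = sd.index[sd == 0].tolist()
    if zero_var and scaling == "auto":
        warnings.warn(
            f"zero-variance column(s) under auto scaling, centered only: "
            f"{', '.join(zero_var)}", stacklevel=2)
    scaler = ScalerParams(mean=mean, sd=sd, scaling=scaling, zero_variance=zero_var)
    scaled = scaler.project(logged, already_log=True)
    return table.replace_values(scaled, transform_state="scaled", scaler=scaler)


def qc_repeatability(table: MetaboliteProfileTable) -> pd.DataFrame:
    """Per-metabolite, per-batch QC repeatability summary.

    For each batch, the relative standard deviation (percent) of each
    metabolite across the post-conditioning QC injections — the first
    five QCs of a batch condition the column and are excluded — and the
    maximum absolute percent difference over repeat/original pairs
    (paired by subject, intervention and hour).  Batches with fewer than
    two usable QC rows get NaN RSDs (summary unavailable).
    """
    metab = table.metabolites
    rows = []
    for batch, grp in table.data.groupby("batch_id", sort=True):
        qc = grp[grp["role"] == "qc"].sort_values("injection_order")
        usable = qc.iloc[5:]  # first five condition the column
        if len(usable) >= 2:
            m = usable[metab].mean()
            s = usable[metab].std(ddof=1)
            rsd = 100.0 * s / m.where(m != 0)
            rsd[s == 0] = 0.0  # identical injections, incl. all-zero columns
        else:
            rsd = pd.Series(np.nan, index=metab)
        reps = grp[grp["role"] == "repeat"]
        exp = grp[grp["role"] == "experimental"]
        diffs = pd.DataFrame(index=metab, columns=range(len(reps)), dtype=float)
        for j, (_, rep) in enumerate(reps.iterrows()):
            orig = exp[(exp["subject_id"] == rep["subject_id"])
                       & (exp["intervention"] == rep["intervention"])
                       & (exp["time_h"] == rep["time_h"])]
            if len(orig) != 1:
                continue
            o = orig[metab].iloc[0]
            r = rep[metab].astype(float)
            diffs[j] = 100.0 * (r - o).abs() / o.where(o != 0)
            diffs.loc[(o == 0) & (r == 0), j] = 0.0
        maxdiff = diffs.max(axis=1) if len(reps) else pd.Series(np.nan, index=metab)
        rows.append(pd.DataFrame({
            "metabolite": metab,
            "batch_id": batch,
            "qc_rsd_percent": rsd.to_numpy(),
            "repeat_max_abs_diff_percent": maxdiff.to_numpy(),
        }))
    if not rows:
        return pd.DataFrame(columns=["metabolite", "batch_id", "qc_rsd_percent",
                                     "repeat_max_abs_diff_percent"])
    return pd.concat(rows, ignore_index=True)
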