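"""Univariate statistics, triple-criterion biomarker selection,
Spearman correlation banding, and paired-design power.

Fold changes are signed ratios of arithmetic group means of the
creatinine-normalized concentrations: +ratio when the comparison mean is
at least the reference mean, otherwise -1/ratio, so increases and
decreases have symmetric magnitudes and |FC| >= 1 always.

The paired test is the Wilcoxon signed-rank test on within-subject
differences: zero differences are dropped, tied absolute differences
are mid-ranked, and the p-value is exact (full enumeration of the 2^n
sign assignments, computed by dynamic programming) for n <= 25 pairs,
switching to the tie-corrected normal approximation above that.

A metabolite is selected as alcohol-responsive when it passes all three
gates at the contrast of interest: VIP >= 1.0, Wilcoxon p <= 0.05 and
|FC| >= 1.5.  No multiple-testing correction gates the selection; a
Benjamini-Hochberg FDR column is emitted for reference only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import MetaboliteProfileTable, UrometError, ValidationError


# ---------------------------------------------------------------------------
# fold change

def signed_fold_change(mean_ref: float, mean_cmp: float) -> float:
    """Signed fold change of a comparison mean relative to a reference.

    FC = mean_cmp/mean_ref when the ratio is >= 1, else -mean_ref/mean_cmp.
    Both means must be positive concentrations.
    """
    if not (mean_ref > 0 and mean_cmp > 0):
        raise ValidationError(
            f"fold change needs positive means, got ref={mean_ref}, "
            f"cmp={mean_cmp}")
    ratio = mean_cmp / mean_ref
    return float(ratio) if ratio >= 1 else float(-1.0 / ratio)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank

@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    statistic: float  # W+ = sum of ranks of positive differences
    n_used: int       # pairs after dropping zero differences
    method: str       # "exact" or "approx"
    degenerate: bool = False  # all differences were zero

    def __float__(self):  # allows float(result)
        return self.p_value


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p by enumerating all sign assignments of the
    (possibly mid-) ranks via dynamic programming.

    Mid-ranks are multiples of 1/2, so doubling makes them integers and
    the distribution of 2*W+ is a convolution of {0, 2r_i} steps.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    counts /= counts.sum()
    cdf = np.cumsum(counts)
    w2 = int(np.rint(2 * w_plus))
    lo = cdf[w2]
    hi = 1.0 - (cdf[w2 - 1] if w2 > 0 else 0.0)
    return min(1.0, 2.0 * min(lo, hi))


@lru_cache(maxsize=64)
def _exact_null_pvalues(n: int) -> np.ndarray:
    """Two-sided p for every integer W+ value, untied ranks 1..n."""
    ranks = np.arange(1, n + 1, dtype=float)
    total = n * (n + 1) // 2
    return np.array([_exact_signed_rank_p(w, ranks) for w in range(total + 1)])


def wilcoxon_signed_rank(x_ref, x_cmp, method: str = "auto") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped; if all differences are zero the result
    is the degenerate p = 1.0.  At least 5 usable pairs are required.
    ``method``: "exact" (enumeration, default for n <= 25), "approx"
    (normal with tie correction) or "auto".
    """
    x_ref = np.asarray(x_ref, dtype=float)
    x_cmp = np.asarray(x_cmp, dtype=float)
    if x_ref.shape != x_cmp.shape or x_ref.ndim != 1:
        raise ValidationError("paired vectors must be 1-D and equal length")
    d = x_cmp - x_ref
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(1.0, 0.0, 0, "exact", degenerate=True)
    n = d.size
    if n < 5:
        raise ValidationError(
            f"need at least 5 non-zero paired differences, got {n}")
    ranks = sps.rankdata(np.abs(d))  # mid-ranks on ties
    w_plus = float(ranks[d > 0].sum())
    if method == "auto":
        method = "exact" if n <= 25 else "approx"
    if method == "exact":
        p = _exact_signed_rank_p(w_plus, ranks)
    elif method == "approx":
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        z = (w_plus - mu) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        p = max(p, np.finfo(float).tiny)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return WilcoxonResult(p, w_plus, n, method)


# ---------------------------------------------------------------------------
# biomarker selection

def select_biomarkers(table: MetaboliteProfileTable, vip: pd.Series,
                      contrast: tuple[int, int] = (0, 1), *,
                      intervention: str = "alcohol",
                      vip_min: float = 1.0, p_max: float = 0.05,
                      abs_fc_min: float = 1.5,
                      method: str = "exact") -> pd.DataFrame:
    """Triple-criterion biomarker selection on one intervention arm.

    Builds one record per metabolite from the creatinine-normalized
    (untransformed) concentrations: VIP at the contrast, Wilcoxon
    signed-rank p and signed fold change at the contrast hours and at
    (0, last hour), and per-hour means and standard deviations.  A
    metabolite is selected when VIP >= ``vip_min``, p <= ``p_max`` and
    |FC| >= ``abs_fc_min`` at the contrast.  Output is sorted by VIP
    descending.
    """
    if not table.normalized:
        raise ValidationError("selection requires creatinine-normalized values")
    if table.transform_state not in ("raw", "imputed"):
        raise ValidationError(
            "selection works on concentration scale, not log/scaled values")
    metab = table.metabolites
    vip = pd.Series(vip)
    if set(vip.index) != set(metab):
        raise ValidationError("VIP vector does not match the metabolite set")
    exp = table.experimental
    exp = exp[exp["intervention"] == intervention]
    times = sorted(exp["time_h"].unique())
    t_ref, t_cmp = contrast
    if t_ref not in times or t_cmp not in times:
        raise ValidationError(f"contrast {contrast} not within design hours {times}")
    t_last = times[-1]

    by_time = {t: exp[exp["time_h"] == t].sort_values("subject_id")
               for t in times}
    subj_ref = by_time[t_ref]["subject_id"].to_numpy()
    for t in (t_cmp, t_last):
        if not np.array_equal(by_time[t]["subject_id"].to_numpy(), subj_ref):
            raise ValidationError(
                f"pairing broken: hours {t_ref} and {t} have different subjects")

    rows = []
    for m in metab:
        rec: dict = {"metabolite": m, "vip": float(vip[m])}
        x0 = by_time[t_ref][m].to_numpy(dtype=float)
        x1 = by_time[t_cmp][m].to_numpy(dtype=float)
        x4 = by_time[t_last][m].to_numpy(dtype=float)
        rec[f"p_{t_ref}_{t_cmp}"] = wilcoxon_signed_rank(x0, x1, method).p_value
        rec[f"fc_{t_ref}_{t_cmp}"] = signed_fold_change(x0.mean(), x1.mean())
        rec[f"p_{t_ref}_{t_last}"] = wilcoxon_signed_rank(x0, x4, method).p_value
        rec[f"fc_{t_ref}_{t_last}"] = signed_fold_change(x0.mean(), x4.mean())
        for t in times:
            xt = by_time[t][m].to_numpy(dtype=float)
            rec[f"mean_{t}"] = float(xt.mean())
            rec[f"sd_{t}"] = float(xt.std(ddof=1))
        rows.append(rec)
    out = pd.DataFrame(rows)
    pcol, fcol = f"p_{t_ref}_{t_cmp}", f"fc_{t_ref}_{t_cmp}"
    out["selected"] = ((out["vip"] >= vip_min) & (out[pcol] <= p_max)
                       & (out[fcol].abs() >= abs_fc_min))
    # reference-only FDR column; never gates selection
    out["fdr_bh"] = _benjamini_hochberg(out[pcol].to_numpy())
    return (out.sort_values("vip", ascending=False, kind="mergesort")
            .reset_index(drop=True))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    cummin = 1.0
    for i in range(m - 1, -1, -1):
        cummin = min(cummin, p[order[i]] * m / (i + 1))
        adj[order[i]] = cummin
    return adj


# ---------------------------------------------------------------------------
# Spearman correlation

BAND_LABELS = ("high_positive", "positive", "neutral", "negative",
               "high_negative")


def correlation_band(r: float) -> str:
    """Fixed colour-band thresholds for a Spearman coefficient:
    high positive r >= 0.6, positive 0.2 <= r < 0.6, neutral
    -0.2 < r < 0.2, negative -0.6 < r <= -0.2, high negative r <= -0.6."""
    if np.isnan(r):
        return "undefined"
    if r >= 0.6:
        return "high_positive"
    if r >= 0.2:
        return "positive"
    if r > -0.2:
        return "neutral"
    if r > -0.6:
        return "negative"
    return "high_negative"


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman matrix with colour bands; ``constant`` lists
    variables whose rho is undefined (zero rank variance)."""

    rho: pd.DataFrame
    band: pd.DataFrame
    constant: list[str]

    @property
    def variables(self) -> list[str]:
        return list(self.rho.columns)

    def to_long(self) -> pd.DataFrame:
        rows = []
        cols = self.variables
        for i, a in enumerate(cols):
            for b in cols[i:]:
                rows.append({"var1": a, "var2": b,
                             "rho": self.rho.loc[a, b],
                             "band": self.band.loc[a, b]})
        return pd.DataFrame(rows)


def spearman_matrix(table: MetaboliteProfileTable,
                    variables: list[str] | None = None, *,
                    include_time: bool = False,
                    intervention: str = "alcohol") -> CorrelationMatrix:
    """Pairwise Spearman rho over all pooled samples of one arm.

    Observations are all experimental samples of the arm across all
    hours (subjects x hours pooled, "over the full period").  With
    ``include_time`` the sampling hour joins as a pseudo-variable, so a
    metabolite's monotone drift over the study reads directly off its
    correlation with time.  Mid-ranks handle ties; constant variables
    get NaN rho and are flagged.
    """
    exp = table.experimental
    exp = exp[exp["intervention"] == intervention]
    if len(exp) < 3:
        raise ValidationError("need at least 3 observations")
    if variables is None:
        variables = table.metabolites
    unknown = [v for v in variables if v not in table.metabolites]
    if unknown:
        raise ValidationError(f"unknown variable(s): {', '.join(unknown)}")
    data = exp[variables].astype(float).copy()
    if include_time:
        data["time"] = exp["time_h"].astype(float).to_numpy()
    cols = list(data.columns)
    const = [c for c in cols if data[c].nunique() <= 1]
    ranks = data.rank(method="average")
    rho = ranks.corr(method="pearson")
    for c in const:
        rho.loc[c, :] = np.nan
        rho.loc[:, c] = np.nan
    np.fill_diagonal(rho.values, 1.0)
    for c in const:
        rho.loc[c, c] = np.nan
    band = rho.map(correlation_band)
    return CorrelationMatrix(rho=rho, band=band, constant=const)


# ---------------------------------------------------------------------------
# paired power

def paired_power(effect_size: float, n: int, alpha: float = 0.05) -> float:
    """Analytic power of the two-sided paired (one-sample) t-test.

    Uses the noncentral t distribution with df = n-1 and noncentrality
    d*sqrt(n), where d is the standardized mean difference.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if effect_size < 0:
        raise ValidationError("effect size must be non-negative")
    if n < 2:
        raise ValidationError("need at least 2 pairs")
    df = n - 1
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    ncp = effect_size * np.sqrt(n)
    power = (1 - sps.nct.cdf(tcrit, df, ncp)) + sps.nct.cdf(-tcrit, df, ncp)
    return float(power)


def paired_power_mc(effect_size: float, n: int, alpha: float = 0.05, *,
                    test: str = "t", n_rep: int = 100_000,
                    seed: int | None = None) -> float:
    """Monte-Carlo power under normal within-pair differences N(d, 1).

    ``test='t'`` simulates the paired t-test (companion check of the
    analytic formula); ``test='wilcoxon'`` simulates the exact Wilcoxon
    signed-rank test under the same normal shift.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_rep, n)) + effect_size
    if test == "t":
        m = x.mean(axis=1)
        s = x.std(axis=1, ddof=1)
        tstat = m / (s / np.sqrt(n))
        p = 2 * sps.t.sf(np.abs(tstat), n - 1)
    elif test == "wilcoxon":
        ranks = sps.rankdata(np.abs(x), axis=1)
        w = np.where(x > 0, ranks, 0.0).sum(axis=1).astype(int)
        p = _exact_null_pvalues(n)[w]
    else:
        raise ValidationError(f"unknown test {test!r}")
    return float((p <= alpha).mean())
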