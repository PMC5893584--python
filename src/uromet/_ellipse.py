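"""Confidence-ellipse parameters for 2-D score clouds.

Only parameters are computed (center, semi-axes, orientation); drawing
is left to the caller.  The contour is the chi-square quantile of a
bivariate normal fitted to the points: with sample covariance S, the
ellipse is {x : (x-m)' S^-1 (x-m) = chi2_2(level)}.  For a confidence
region of the *centroid* the covariance of the mean, S/n, is used
instead of S.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def confidence_ellipse(points: np.ndarray, level: float = 0.95,
                       scope: str = "scores") -> dict:
    """Ellipse parameters for 2-D points.

    Returns a dict with center ``(cx, cy)``, semi-axes ``a >= b`` and
    ``angle_deg`` (orientation of the major axis, degrees counter-
    clockwise from the first score axis).  ``scope='centroid'`` shrinks
    the covariance by 1/n to describe the uncertainty of the mean.
    Degenerate clouds (n < 2 or zero variance) give zero axes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("confidence_ellipse expects an (n, 2) array")
    n = pts.shape[0]
    center = pts.mean(axis=0)
    out = {"cx": float(center[0]), "cy": float(center[1]),
           "a": 0.0, "b": 0.0, "angle_deg": 0.0}
    if n < 2:
        return out
    cov = np.cov(pts, rowvar=False)
    if scope == "centroid":
        cov = cov / n
    elif scope != "scores":
        raise ValueError(f"unknown scope {scope!r}")
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    q = stats.chi2.ppf(level, df=2)
    # eigh returns ascending order: major axis last
    out["a"] = float(np.sqrt(vals[1] * q))
    out["b"] = float(np.sqrt(vals[0] * q))
    out["angle_deg"] = float(np.degrees(np.arctan2(vecs[1, 1], vecs[0, 1])))
    return out
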