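"""Cohort-level statistics over period metrics.

Implements the study-style statistical layer: repeated-measures (within-
subject) correlation, a night-to-postprandial Spearman screen with a
significance/trend band, one-way diet ANOVA, a two-sided variance F-test
and a standardized-metric PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RmCorrResult",
    "PCAResult",
    "rm_correlation",
    "spearman_screen",
    "diet_anova",
    "variance_f_test",
    "pca_metrics",
    "benjamini_hochberg",
]

#: Significance / trend thresholds used when flagging screen results.
P_SIGNIFICANT = 0.05
P_TREND = 0.10


@dataclass(frozen=True)
class RmCorrResult:
    r: float
    df: int
    p: float
    n_subjects: int
    n_obs: int


def rm_correlation(x, y, subject) -> RmCorrResult:
    """Repeated-measures correlation of paired observations.

    Both variables are centered within subject; ``r`` is the Pearson
    correlation of the pooled centered values, with ``df = n_obs -
    n_subjects - 1`` and a two-sided t-based p-value.  Subjects with fewer
    than 2 observations are dropped with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subject = np.asarray(subject)
    if not (len(x) == len(y) == len(subject)):
        raise ValueError("x, y and subject must have equal length")
    keep = np.ones(len(x), dtype=bool)
    for s in pd.unique(subject):
        mask = subject == s
        if mask.sum() < 2:
            warnings.warn(f"subject {s!r} has < 2 observations; dropped", stacklevel=2)
            keep &= ~mask
    x, y, subject = x[keep], y[keep], subject[keep]
    subjects = pd.unique(subject)
    if len(subjects) < 1 or len(x) < 3:
        raise ValueError("need at least one subject with >= 2 observations and >= 3 points")
    xc = np.empty_like(x)
    yc = np.empty_like(y)
    for s in subjects:
        mask = subject == s
        xc[mask] = x[mask] - x[mask].mean()
        yc[mask] = y[mask] - y[mask].mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero within-subject variance: correlation undefined")
    r = float((xc * yc).sum() / denom)
    df = len(x) - len(subjects) - 1
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    r_clip = min(max(r, -1.0), 1.0)
    if abs(r_clip) >= 1.0:
        p = 0.0
    else:
        t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return RmCorrResult(r=r, df=df, p=p, n_subjects=len(subjects), n_obs=len(x))


def _flag(p: float) -> str:
    if p <= P_SIGNIFICANT:
        return "significant"
    if p <= P_TREND:
        return "trend"
    return "ns"


def spearman_screen(
    night: pd.DataFrame,
    post: pd.DataFrame,
    id_col: str = "animal_id",
    fdr: bool = False,
) -> pd.DataFrame:
    """Rank-correlate every night metric with every postprandial metric.

    Both tables must carry one row per animal; rows are matched on
    ``id_col``.  Output columns: ``post_metric, night_metric, rho, p, flag``
    with flags ``significant`` (p <= 0.05), ``trend`` (0.05 < p <= 0.10) or
    ``ns``.  Constant columns are skipped with a warning.  This is a raw,
    uncorrected screen; ``fdr=True`` adds a ``p_adjusted`` column
    (Benjamini-Hochberg) without changing the flags.
    """
    merged = night.merge(post, on=id_col, suffixes=("_night", "_post"))
    if len(merged) < 4:
        raise ValueError(f"need >= 4 matched animals, got {len(merged)}")
    night_cols = [c for c in night.columns if c != id_col]
    post_cols = [c for c in post.columns if c != id_col]
    rows = []
    for pc in post_cols:
        pv = merged[pc + "_post" if pc + "_post" in merged else pc].to_numpy(float)
        for nc in night_cols:
            nv = merged[nc + "_night" if nc + "_night" in merged else nc].to_numpy(float)
            ok = np.isfinite(pv) & np.isfinite(nv)
            if ok.sum() < 4:
                continue
            if np.all(pv[ok] == pv[ok][0]) or np.all(nv[ok] == nv[ok][0]):
                warnings.warn(
                    f"constant metric column in pair ({pc}, {nc}); skipped", stacklevel=2
                )
                continue
            rho, p = sps.spearmanr(pv[ok], nv[ok])
            rows.append(
                {"post_metric": pc, "night_metric": nc, "rho": float(rho),
                 "p": float(p), "n": int(ok.sum()), "flag": _flag(float(p))}
            )
    out = pd.DataFrame(rows, columns=["post_metric", "night_metric", "rho", "p", "n", "flag"])
    if fdr and len(out):
        out["p_adjusted"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def diet_anova(metric, labels) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of a metric across groups.

    Returns ``(F, p)``.  Every group needs at least 2 observations.
    """
    metric = np.asarray(metric, dtype=float)
    labels = np.asarray(labels)
    groups = [metric[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, values in zip(pd.unique(labels), groups):
        if len(values) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def variance_f_test(a, b) -> tuple[float, float]:
    """Two-sided F-test comparing the variances of two samples.

    ``F = var(a) / var(b)`` with sample (n-1) variances; the p-value is
    ``2 * min(P(F' <= F), P(F' >= F))`` under F(n_a - 1, n_b - 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 observations")
    vb = np.var(b, ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator sample")
    f = float(np.var(a, ddof=1) / vb)
    dist = sps.f(len(a) - 1, len(b) - 1)
    p = float(2.0 * min(dist.cdf(f), dist.sf(f)))
    return f, min(p, 1.0)


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray  # rows x components
    loadings: np.ndarray  # metrics x components
    explained_variance_ratio: np.ndarray
    columns: tuple[str, ...]

    def reconstruct(self) -> np.ndarray:
        """Standardized table rebuilt from all components."""
        return self.scores @ self.loadings.T


def pca_metrics(table: pd.DataFrame) -> PCAResult:
    """PCA of a metric table after zero-mean / unit-sample-SD standardization.

    No rotation is applied; explained-variance fractions sum to 1.  Constant
    columns are rejected by name, missing cells are rejected outright.
    """
    numeric = table.select_dtypes(include=[np.number])
    if numeric.shape[0] < 3 or numeric.shape[1] < 2:
        raise ValueError("need at least 3 rows and 2 numeric metric columns")
    if numeric.isna().any().any():
        bad = numeric.columns[numeric.isna().any()].tolist()
        raise ValueError(f"missing cells in columns {bad}")
    sd = numeric.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant metric column(s): {constant}")
    z = ((numeric - numeric.mean()) / sd).to_numpy()
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u * s
    var = s**2
    return PCAResult(
        scores=scores,
        loadings=vt.T,
        explained_variance_ratio=var / var.sum(),
        columns=tuple(numeric.columns),
    )


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
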