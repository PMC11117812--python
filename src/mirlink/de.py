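"""Negative-binomial two-group differential expression.

A DESeq2-style engine, not a bit-exact clone: median-of-ratios size
factors, per-feature NB dispersion moderated toward a mean-dispersion
trend, a two-group NB GLM fitted by iteratively reweighted least squares
with the size factors as offsets, and a two-sided Wald test on the group
coefficient with Benjamini-Hochberg adjustment. Features failing a
low-count filter are excluded from the adjustment and flagged with an
undefined adjusted p.

The reported ``log2fc`` is the fitted group coefficient on the log2 scale
for the first group over the second (no pseudocount, no shrinkage of the
estimate itself).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix

__all__ = ["size_factors", "bh_adjust", "de_test", "filter_de"]

DE_RESULT_COLUMNS = ["base_mean", "log2fc", "se", "stat", "pvalue", "padj"]

_LN2 = np.log(2.0)


def size_factors(counts: CountMatrix | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios per-sample scale factors.

    For each feature positive in every sample, form count / geometric mean
    across samples; the sample's factor is the median of those ratios.
    Features with any zero are excluded from the reference. The factors are
    left exactly as the median step produces them (their geometric mean is
    1 only up to the estimator's own scale; no renormalization is applied).
    """
    values = counts.values if isinstance(counts, CountMatrix) else counts.to_numpy()
    values = np.asarray(values, dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no feature is positive in every sample; size factors undefined")
    ref = values[all_positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    log_ratios = np.log(ref) - log_geo_mean[:, None]
    return np.exp(np.median(log_ratios, axis=0))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are ignored (and returned as NaN); adjusted values are
    monotone non-decreasing in p-value rank and clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    result = np.empty(m)
    result[order] = np.clip(adj, 0.0, 1.0)
    out[mask] = result
    return out


def _dispersion_estimates(
    q: np.ndarray, group: np.ndarray, inv_sf_mean: float
) -> np.ndarray:
    """Moderated NB dispersions from normalized counts.

    Method-of-moments per-feature estimates (pooled within-group variance)
    are shrunk in log space toward a parametric trend a0 + a1/mu fitted to
    binned medians, then floored at the trend: small-n moment estimates
    scatter widely below the trend, and letting them pull dispersion down
    makes the Wald test anti-conservative.
    """
    n = q.shape[1]
    mu = q.mean(axis=1)
    groups = np.unique(group)
    ss = np.zeros(q.shape[0])
    df = 0
    for g in groups:
        cols = group == g
        ng = int(cols.sum())
        if ng > 1:
            ss += q[:, cols].var(axis=1, ddof=1) * (ng - 1)
            df += ng - 1
    var_within = ss / max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (var_within - mu * inv_sf_mean) / mu**2
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, np.nan)
    alpha_floor = 1e-8
    alpha_mom_c = np.clip(alpha_mom, alpha_floor, 10.0)

    # parametric trend over mean bins
    usable = (mu > 0) & ~np.isnan(alpha_mom)
    a0, a1 = 0.01, 1.0
    if usable.sum() >= 20:
        log_mu = np.log(mu[usable])
        bins = np.quantile(log_mu, np.linspace(0, 1, 21))
        bins[-1] += 1e-9
        idx = np.clip(np.digitize(log_mu, bins) - 1, 0, 19)
        bin_mu, bin_alpha = [], []
        for b in range(20):
            sel = idx == b
            if sel.sum() >= 5:
                bin_mu.append(np.exp(log_mu[sel]).mean())
                bin_alpha.append(np.median(alpha_mom_c[usable][sel]))
        if len(bin_mu) >= 3:
            A = np.column_stack([np.ones(len(bin_mu)), 1.0 / np.asarray(bin_mu)])
            coef, *_ = np.linalg.lstsq(A, np.asarray(bin_alpha), rcond=None)
            a0 = max(float(coef[0]), alpha_floor)
            a1 = max(float(coef[1]), 0.0)
    with np.errstate(divide="ignore"):
        alpha_trend = a0 + a1 / np.maximum(mu, 1e-12)

    # shrink in log space with prior weight comparable to the residual df
    w_prior = 4.0
    log_shrunk = (df * np.log(alpha_mom_c) + w_prior * np.log(alpha_trend)) / (
        df + w_prior
    )
    alpha = np.exp(log_shrunk)
    alpha = np.maximum(alpha, alpha_trend)  # never below the trend
    alpha = np.where(np.isnan(alpha_mom), alpha_trend, alpha)
    return np.clip(alpha, alpha_floor, 10.0)


def _nb_irls(
    counts: np.ndarray,
    offsets: np.ndarray,
    x: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit log mu = offset + b0 + b1*x per feature (vectorized IRLS).

    Returns (b0, b1, se_b1) in natural-log units. Coefficients are bounded
    to keep features with an all-zero group finite.
    """
    n_feat, n_samp = counts.shape
    b0 = np.log(np.maximum(counts.mean(axis=1) / np.exp(offsets).mean(), 1e-8))
    b1 = np.zeros(n_feat)
    bound = 30.0
    xx = x.astype(float)
    for _ in range(max_iter):
        eta = offsets[None, :] + b0[:, None] + b1[:, None] * xx[None, :]
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (b0[:, None] + b1[:, None] * xx[None, :]) + (counts - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * xx).sum(axis=1)
        swxx = (w * xx * xx).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * xx * z).sum(axis=1)
        det = sw * swxx - swx**2
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        new_b0 = (swxx * swz - swx * swxz) / det
        new_b1 = (sw * swxz - swx * swz) / det
        new_b0 = np.clip(np.where(np.isfinite(new_b0), new_b0, b0), -bound, bound)
        new_b1 = np.clip(np.where(np.isfinite(new_b1), new_b1, b1), -bound, bound)
        delta = np.maximum(np.abs(new_b0 - b0), np.abs(new_b1 - b1))
        b0, b1 = new_b0, new_b1
        if np.nanmax(delta, initial=0.0) < tol:
            break
    eta = offsets[None, :] + b0[:, None] + b1[:, None] * xx[None, :]
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    w = mu / (1.0 + alpha[:, None] * mu)
    sw = w.sum(axis=1)
    swx = (w * xx).sum(axis=1)
    swxx = (w * xx * xx).sum(axis=1)
    det = sw * swxx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se_b1 = np.sqrt(np.where(det > 0, sw / det, np.nan))
    return b0, b1, se_b1


def de_test(
    counts: CountMatrix,
    meta: pd.DataFrame,
    groups: tuple[str, str] | None = None,
    min_base_mean: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB Wald differential expression.

    ``groups`` names (numerator, denominator); by default the two group
    labels in order of first appearance in ``meta``. Returns a frame
    indexed by feature with base_mean, log2fc, se, stat, pvalue, padj.
    Features with mean normalized count below ``min_base_mean`` keep their
    p-value but get ``padj`` = NaN (independent low-count filter).
    """
    meta = meta.set_index("sample_id").loc[counts.sample_ids].reset_index()
    if groups is None:
        seen = list(dict.fromkeys(meta["group"]))
        if len(seen) != 2:
            raise ValueError(f"need exactly two groups, found {seen}")
        groups = (seen[0], seen[1])
    g_num, g_den = groups
    labels = meta["group"].to_numpy()
    n_num = int((labels == g_num).sum())
    n_den = int((labels == g_den).sum())
    if n_num < 2 or n_den < 2:
        raise ValueError(f"both groups need >= 2 samples (got {n_num} vs {n_den})")
    if n_num + n_den != len(labels):
        extra = sorted(set(labels) - set(groups))
        raise ValueError(f"samples with unknown group label(s): {extra}")

    sf = size_factors(counts)
    values = counts.values.astype(float)
    q = values / sf[None, :]
    base_mean = q.mean(axis=1)
    # +1/2 vs -1/2 coding keeps the intercept at the midpoint
    x = np.where(labels == g_num, 0.5, -0.5)

    alpha = _dispersion_estimates(q, labels, float(np.mean(1.0 / sf)))
    _, b1, se_b1 = _nb_irls(values, np.log(sf), x, alpha)

    log2fc = b1 / _LN2
    se = se_b1 / _LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = b1 / se_b1
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))

    # degenerate features: identical normalized counts in every sample
    num_mean = q[:, x > 0].mean(axis=1)
    den_mean = q[:, x < 0].mean(axis=1)
    constant = np.ptp(q, axis=1) == 0
    log2fc = np.where(constant, 0.0, log2fc)
    stat = np.where(constant, 0.0, stat)
    pvalue = np.where(constant, 1.0, pvalue)
    equal_means = num_mean == den_mean
    log2fc = np.where(equal_means, 0.0, log2fc)

    all_zero = values.sum(axis=1) == 0
    pvalue = np.where(all_zero, np.nan, pvalue)

    tested = (base_mean >= min_base_mean) & ~np.isnan(pvalue)
    padj = np.full(len(base_mean), np.nan)
    padj[tested] = bh_adjust(pvalue[tested])

    result = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=pd.Index(counts.feature_ids, name="feature_id"),
    )
    result.attrs["groups"] = groups
    result.attrs["size_factors"] = dict(zip(counts.sample_ids, sf.tolist()))
    return result


def filter_de(
    result: pd.DataFrame,
    lfc_min: float = 0.5,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Significant features: |log2fc| > lfc_min AND p < alpha, both strict.

    The retained frame carries a ``direction`` column ('up'/'down' by the
    sign of log2fc).
    """
    if lfc_min < 0:
        raise ValueError("lfc_min must be >= 0")
    if result.empty:
        out = result.copy()
        out["direction"] = pd.Series(dtype=str)
        return out
    p = result["padj"] if use_adjusted else result["pvalue"]
    keep = (result["log2fc"].abs() > lfc_min) & (p < alpha)
    keep &= p.notna()
    out = result[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out
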