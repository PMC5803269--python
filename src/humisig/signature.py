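"""Derivation of a cell-type-enriched gene signature from purified vs bulk data.

The contrast of interest is mean log2 expression in purified cells minus
mean log2 expression in bulk tissue. Before contrasting, per-sample
log-ratios against the grand mean are cleaned of residual GC-content and
gene-length artifacts by robust (Huber M-estimator) regression. Significance
uses a two-group moderated t statistic: per-gene variances are shrunk toward
an empirical-Bayes prior estimated from the distribution of log sample
variances by method of moments, and p-values are Benjamini-Hochberg
adjusted. The signature proper is the set of genes whose purified-over-bulk
fold change exceeds a threshold (4 by default, boundary inclusive); a
stricter subset additionally requires adjusted significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

from .exprio import ExpressionMatrix

_HUBER_T = 1.345  # 95% gaussian efficiency


@dataclass
class NormalizationFit:
    """Per-sample robust artifact fit: r ~ intercept + gc + log10(length)."""

    coefficients: pd.DataFrame  # samples x [intercept, gc_fraction, log10_length]
    residuals: pd.DataFrame  # genes x samples: log-ratios minus fitted artifact


def residual_normalize(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[ExpressionMatrix, NormalizationFit]:
    """Remove per-sample GC/length artifacts from a log2 matrix.

    For each sample s the log-ratio r_gs = x_gs - mean_{s'}(x_gs') is
    regressed on (gc_fraction, log10 length) with a Huber M-estimator
    (tuning constant 1.345, IRLS); the fitted artifact component (including
    the intercept of the ratio fit) is subtracted from x_gs.

    Requires at least 10 genes; the robust fit is unstable below that.
    """
    if m.scale not in ("log2", "normalized"):
        raise ValueError("residual normalization requires a log2-scale matrix")
    if m.n_genes < 10:
        raise ValueError("refusing to fit artifact model on fewer than 10 genes")
    missing = m.gene_ids.difference(ann.index)
    if len(missing):
        raise ValueError(f"annotation missing for genes {list(missing[:5])}")
    sub = ann.loc[m.gene_ids]
    X = sm.add_constant(
        np.column_stack([
            sub["gc_fraction"].to_numpy(dtype=float),
            np.log10(sub["length_bp"].to_numpy(dtype=float)),
        ])
    )
    vals = m.values.to_numpy(dtype=float)
    grand_mean = vals.mean(axis=1)
    ratios = vals - grand_mean[:, None]

    coefs = np.empty((m.n_samples, 3))
    fitted = np.empty_like(ratios)
    for j in range(m.n_samples):
        res = sm.RLM(ratios[:, j], X, M=sm.robust.norms.HuberT(t=_HUBER_T)).fit(
            maxiter=max_iter, tol=tol
        )
        coefs[j] = res.params
        fitted[:, j] = X @ res.params
    normalized = ExpressionMatrix(
        pd.DataFrame(vals - fitted, index=m.gene_ids, columns=m.sample_ids),
        scale="normalized",
    )
    fit = NormalizationFit(
        coefficients=pd.DataFrame(
            coefs,
            index=m.sample_ids,
            columns=["intercept", "gc_fraction", "log10_length"],
        ),
        residuals=pd.DataFrame(ratios - fitted, index=m.gene_ids, columns=m.sample_ids),
    )
    return normalized, fit


def fold_change_contrast(
    purified: ExpressionMatrix, bulk: ExpressionMatrix
) -> pd.Series:
    """Per-gene log2 fold change: mean over purified samples minus mean over bulk.

    Both matrices must be on a log scale; genes are intersected (purified
    order kept). Raises on an empty intersection.
    """
    for mat, label in ((purified, "purified"), (bulk, "bulk")):
        if mat.scale == "raw":
            raise ValueError(f"{label} matrix must be log2 or normalized scale")
    common = purified.gene_ids.intersection(bulk.gene_ids)
    if len(common) == 0:
        raise ValueError("empty gene intersection between purified and bulk")
    common = purified.gene_ids[purified.gene_ids.isin(common)]
    lfc = (
        purified.values.loc[common].mean(axis=1)
        - bulk.values.loc[common].mean(axis=1)
    )
    lfc.name = "log2_fc"
    return lfc


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior df d0, prior variance s0^2).

    Models s2_g ~ s0^2 * F(df, d0) via the first two moments of
    log(s2_g): e_g = log(s2_g) - digamma(df/2) + log(df/2) has mean
    log(s0^2) + log(d0/2) - digamma(d0/2) and variance
    trigamma(df/2) + trigamma(d0/2). Zero variances are excluded from the
    fit. Returns (inf, exp(mean e)) when the observed spread of log s2 is
    no larger than the chi-square sampling contribution.
    """
    s2 = np.asarray(s2, dtype=float)
    s2pos = s2[s2 > 0]
    if s2pos.size < 2:
        return np.inf, float(s2pos.mean()) if s2pos.size else 1.0
    e = np.log(s2pos) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    resid_var = e_var - float(special.polygamma(1, df / 2.0))
    if resid_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(resid_var)
    if not np.isfinite(d0):
        return np.inf, float(np.exp(e_mean))
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def shrink_variance(s2, df: float, prior_df: float, prior_var: float):
    """Posterior variance s2_post = (d0*s0^2 + d*s2) / (d0 + d).

    ``prior_df`` may be inf, in which case the prior variance is returned.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(prior_df):
        return np.full_like(s2, prior_var)
    return (prior_df * prior_var + df * s2) / (prior_df + df)


def moderated_t(
    purified: ExpressionMatrix,
    bulk: ExpressionMatrix,
    weights: pd.DataFrame | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t statistics, purified minus bulk.

    Per gene: group means (optionally precision-weighted), pooled residual
    variance s2_g on d = n1 + n2 - 2 df, empirical-Bayes shrinkage
    s2_post = (d0*s0^2 + d*s2_g) / (d0 + d) with (d0, s0^2) estimated from
    the log-variance distribution (``prior_df`` overrides the estimated d0;
    pass 0 for the ordinary t statistic). The statistic is
    delta / sqrt(s2_post * (1/n1 + 1/n2)) referred to a t distribution on
    d + d0 df.

    Returns a DataFrame with columns log2_fc, mod_t, p_value, s2, s2_post;
    the fitted prior is stored in ``attrs`` ("prior_df", "prior_var").

    Genes with zero variance in both groups: t undefined -> p = 1 when the
    mean difference is 0; otherwise the shrunk variance (floored at s0^2)
    is used, avoiding spurious infinities.
    """
    for mat, label in ((purified, "purified"), (bulk, "bulk")):
        if mat.n_samples < 2:
            raise ValueError(f"{label} group needs at least 2 samples")
        if mat.scale == "raw":
            raise ValueError(f"{label} matrix must be on a log scale")
    common = purified.gene_ids.intersection(bulk.gene_ids)
    if len(common) == 0:
        raise ValueError("empty gene intersection")
    common = purified.gene_ids[purified.gene_ids.isin(common)]
    x1 = purified.values.loc[common].to_numpy(dtype=float)
    x2 = bulk.values.loc[common].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    df_resid = n1 + n2 - 2

    if weights is None:
        m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
        rss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
        eff1, eff2 = float(n1), float(n2)
        eff1 = np.full(len(common), eff1)
        eff2 = np.full(len(common), eff2)
    else:
        w1 = weights.loc[common, purified.sample_ids].to_numpy(dtype=float)
        w2 = weights.loc[common, bulk.sample_ids].to_numpy(dtype=float)
        if (w1 <= 0).any() or (w2 <= 0).any():
            raise ValueError("weights must be strictly positive")
        # normalize to mean 1 within each gene so s2 stays on the data scale
        wall = np.hstack([w1, w2])
        wall = wall / wall.mean(axis=1, keepdims=True)
        w1, w2 = wall[:, :n1], wall[:, n1:]
        m1 = (w1 * x1).sum(axis=1) / w1.sum(axis=1)
        m2 = (w2 * x2).sum(axis=1) / w2.sum(axis=1)
        rss = (w1 * (x1 - m1[:, None]) ** 2).sum(axis=1) + (
            w2 * (x2 - m2[:, None]) ** 2
        ).sum(axis=1)
        eff1, eff2 = w1.sum(axis=1), w2.sum(axis=1)

    s2 = rss / df_resid
    delta = m1 - m2

    if prior_df is not None:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s2, df_resid) if d0 > 0 else (np.nan, 0.0)
    else:
        d0, s0_sq = fit_variance_prior(s2, df_resid)

    s2_post = shrink_variance(s2, df_resid, d0, s0_sq)
    total_df = np.inf if np.isinf(d0) else df_resid + d0

    se_factor = 1.0 / eff1 + 1.0 / eff2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(s2_post * se_factor)
    p = 2.0 * stats.t.sf(np.abs(t), df=total_df)

    degenerate = s2_post <= 0
    if degenerate.any():
        t = np.where(degenerate & (delta == 0), 0.0, t)
        p = np.where(degenerate & (delta == 0), 1.0, p)
        p = np.where(degenerate & (delta != 0), 0.0, p)

    out = pd.DataFrame(
        {
            "log2_fc": delta,
            "mod_t": t,
            "p_value": p,
            "s2": s2,
            "s2_post": s2_post,
        },
        index=common,
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    out.attrs["residual_df"] = df_resid
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Input must lie in [0, 1]; output is the classical step-up sequence,
    monotone in sorted order and capped at 1. Accepts any array-like;
    returns an ndarray aligned with the input order (a Series in, a Series
    out).
    """
    is_series = isinstance(p_values, pd.Series)
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return pd.Series(dtype=float) if is_series else p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(adj_sorted, 1.0)
    if is_series:
        return pd.Series(adj, index=p_values.index, name="adj_p")
    return adj


def derive_signature(
    log2_fc: pd.Series,
    mod_results: pd.DataFrame,
    fc_threshold: float = 4.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assemble the signature table from the contrast and moderated-t results.

    ``in_fc_set``: log2_fc >= log2(fc_threshold), one-sided (purified above
    bulk), boundary inclusive. ``in_pval_set``: additionally BH-adjusted
    p < alpha. Set sizes are stored in ``attrs`` ("n_fc_set", "n_pval_set").
    """
    if not log2_fc.index.equals(mod_results.index):
        common = log2_fc.index.intersection(mod_results.index)
        if len(common) == 0:
            raise ValueError("log2_fc and moderated-t results share no genes")
        log2_fc = log2_fc.loc[common]
        mod_results = mod_results.loc[common]
    adj_p = bh_adjust(mod_results["p_value"])
    in_fc = log2_fc >= np.log2(fc_threshold)
    in_pval = in_fc & (adj_p < alpha)
    out = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "mod_t": mod_results["mod_t"],
            "p_value": mod_results["p_value"],
            "adj_p": adj_p,
            "in_fc_set": in_fc,
            "in_pval_set": in_pval,
        }
    )
    out.attrs["n_fc_set"] = int(in_fc.sum())
    out.attrs["n_pval_set"] = int(in_pval.sum())
    out.attrs["fc_threshold"] = fc_threshold
    out.attrs["alpha"] = alpha
    return out
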