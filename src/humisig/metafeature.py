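"""Sample-level gene-set meta-feature and its association with traits.

A gene set's collective expression in a tissue sample is summarized as one
scalar per sample: each member gene is standardized to unit variance across
samples (no centering, following the construction it emulates) and the
standardized values are averaged over the set. The score is then related to
clinicopathological traits by univariate linear regression, one trait per
row, reporting estimate, standard error, t-value and two-sided p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exprio import ExpressionMatrix

ASSOCIATION_COLUMNS = ["trait", "estimate", "std_error", "t_value", "p_value", "n", "note"]


@dataclass
class MetaFeatureScore:
    """Per-sample scalar summary of a gene set's collective expression."""

    scores: pd.Series  # indexed by sample id
    gene_set: set[str]
    n_genes_used: int


def metafeature_score(m: ExpressionMatrix, gene_set) -> MetaFeatureScore:
    """Average of variance-standardized member genes, per sample.

    Genes in the set but absent from the matrix are ignored; genes with zero
    across-sample variance cannot be standardized and are dropped with a
    warning. Raises if no usable gene remains.
    """
    genes = [g for g in m.gene_ids if g in set(gene_set)]
    if not genes:
        raise ValueError("gene set does not intersect the expression matrix")
    sub = m.values.loc[genes]
    sds = sub.std(axis=1, ddof=1)
    zero_var = sds.index[sds == 0].tolist()
    if zero_var:
        warnings.warn(
            f"dropping {len(zero_var)} zero-variance genes from meta-feature",
            stacklevel=2,
        )
        sub = sub.drop(index=zero_var)
        sds = sds.drop(index=zero_var)
    if sub.shape[0] == 0:
        raise ValueError("all gene-set genes have zero variance")
    standardized = sub.div(sds, axis=0)
    scores = standardized.mean(axis=0)
    scores.name = "metafeature"
    return MetaFeatureScore(scores=scores, gene_set=set(gene_set), n_genes_used=sub.shape[0])


def _univariate_fit(y: np.ndarray, x: np.ndarray) -> dict:
    """OLS of y on (1, x); returns estimate/SE/t/p with degenerate flags."""
    n = y.size
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        return {
            "estimate": np.nan, "std_error": np.nan, "t_value": np.nan,
            "p_value": np.nan, "n": n, "note": "not_estimable_constant_trait",
        }
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    rss = float((resid**2).sum())
    note = ""
    if n <= 2:
        return {
            "estimate": slope, "std_error": np.nan, "t_value": np.nan,
            "p_value": np.nan, "n": n, "note": "not_estimable_df",
        }
    sigma2 = rss / (n - 2)
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0.0 or np.isclose(rss, 0.0, atol=1e-300):
        return {
            "estimate": slope, "std_error": 0.0,
            "t_value": np.inf if slope != 0 else np.nan,
            "p_value": 0.0 if slope != 0 else np.nan,
            "n": n, "note": "degenerate_exact_fit",
        }
    t = slope / se
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return {"estimate": slope, "std_error": se, "t_value": float(t),
            "p_value": p, "n": n, "note": note}


def associate_traits(score: MetaFeatureScore, traits: pd.DataFrame) -> pd.DataFrame:
    """Univariate regressions of the meta-feature on each trait.

    For every trait column, missing values are dropped pairwise, the linear
    model score ~ trait is fit (binary traits coded 0/1, allele counts
    0/1/2 numeric dosages), and one row per trait is emitted in the layout
    Trait / Estimate / Std. error / t-value / p-value. Traits with fewer
    than 3 non-missing values or zero variance are reported as not
    estimable rather than raising.
    """
    common = score.scores.index.intersection(traits.index)
    if len(common) == 0:
        raise ValueError("no shared samples between score and trait table")
    rows = []
    for trait in traits.columns:
        y = score.scores.loc[common]
        x = pd.to_numeric(traits.loc[common, trait], errors="coerce")
        mask = x.notna() & y.notna()
        if int(mask.sum()) < 3:
            rows.append({"trait": trait, "estimate": np.nan, "std_error": np.nan,
                         "t_value": np.nan, "p_value": np.nan,
                         "n": int(mask.sum()), "note": "not_estimable_too_few"})
            continue
        fit = _univariate_fit(y[mask].to_numpy(dtype=float), x[mask].to_numpy(dtype=float))
        fit["trait"] = trait
        rows.append(fit)
    return pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
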