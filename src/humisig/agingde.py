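"""Cross-dataset differential expression between two purified-cell datasets.

Harmonizes an aged and a middle-aged microglia expression dataset onto the
genes reliably detected in both (abundance above a detection threshold in a
minimum fraction of samples of each dataset), optionally quantile-normalizes
the pooled samples to neutralize protocol differences, and classifies genes
as up- or down-regulated with aging using the moderated-t machinery with
|log2 fold change| and adjusted-significance thresholds (strict
inequalities: logFC > 2 or < -2, adjusted p < 0.05 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exprio import ExpressionMatrix, log_transform
from .signature import bh_adjust, moderated_t


@dataclass
class HarmonizedPair:
    """Two log2 expression matrices on an identical, ordered gene universe."""

    a: ExpressionMatrix  # aged
    b: ExpressionMatrix  # reference (middle-aged)
    detect_threshold: float
    min_detected_fraction: float
    quantile_aligned: bool


def _detected(m: ExpressionMatrix, threshold: float, min_fraction: float) -> pd.Series:
    frac = (m.values >= threshold).mean(axis=1)
    return frac >= min_fraction


def _quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Map every sample onto the mean of the sorted columns (classic QN).

    Tied values within a sample receive the mean reference value of their
    average rank via linear interpolation.
    """
    arr = values.to_numpy(dtype=float)
    n = arr.shape[0]
    reference = np.sort(arr, axis=0).mean(axis=1)
    grid = np.arange(1, n + 1, dtype=float)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = pd.Series(arr[:, j]).rank(method="average").to_numpy()
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def harmonize(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    detect_threshold: float = 0.1,
    min_detected_fraction: float = 0.5,
    quantile_align: bool = True,
    pseudocount: float = 1.0,
) -> HarmonizedPair:
    """Restrict both datasets to reliably detected genes and align scales.

    A gene is kept iff its value is at least ``detect_threshold`` in at
    least ``min_detected_fraction`` of the samples of BOTH datasets,
    evaluated on each matrix's own scale (raw matrices are subsequently
    log2-transformed). With ``quantile_align`` every pooled sample is mapped
    onto the common quantile reference, so the two datasets' per-sample
    distributions match exactly.
    """
    if (a.scale == "raw") != (b.scale == "raw"):
        raise ValueError("datasets must share a scale before harmonization")
    det_a = _detected(a, detect_threshold, min_detected_fraction)
    det_b = _detected(b, detect_threshold, min_detected_fraction)
    common = a.gene_ids.intersection(b.gene_ids)
    keep = [g for g in a.gene_ids if g in set(common) and det_a[g] and det_b[g]]
    if not keep:
        raise ValueError("no gene reliably detected in both datasets")
    a_sub = a.subset_genes(keep)
    b_sub = b.subset_genes(keep)
    if a_sub.scale == "raw":
        a_sub = log_transform(a_sub, pseudocount)
        b_sub = log_transform(b_sub, pseudocount)
    if quantile_align:
        pooled = pd.concat([a_sub.values, b_sub.values], axis=1)
        qn = _quantile_normalize(pooled)
        a_sub = ExpressionMatrix(qn[a_sub.sample_ids.tolist()], scale="log2")
        b_sub = ExpressionMatrix(qn[b_sub.sample_ids.tolist()], scale="log2")
    return HarmonizedPair(
        a=a_sub,
        b=b_sub,
        detect_threshold=detect_threshold,
        min_detected_fraction=min_detected_fraction,
        quantile_aligned=quantile_align,
    )


def differential_expression(
    pair: HarmonizedPair,
    logfc_threshold: float = 2.0,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated-t contrast of the harmonized pair with up/down classification.

    log2_fc is dataset a minus dataset b (aged minus reference). A gene is
    ``up`` iff log2_fc > logfc_threshold and BH-adjusted p < alpha,
    ``down`` symmetrically (strict inequalities), otherwise ``ns``.
    Classification counts are stored in ``attrs``.
    """
    res = moderated_t(pair.a, pair.b, prior_df=prior_df)
    adj_p = bh_adjust(res["p_value"])
    lfc = res["log2_fc"]
    up = (lfc > logfc_threshold) & (adj_p < alpha)
    down = (lfc < -logfc_threshold) & (adj_p < alpha)
    cls = np.where(up, "up", np.where(down, "down", "ns"))
    out = pd.DataFrame(
        {
            "log2_fc": lfc,
            "mod_t": res["mod_t"],
            "p_value": res["p_value"],
            "adj_p": adj_p,
            "class": cls,
        },
        index=res.index,
    )
    out.attrs["n_up"] = int(up.sum())
    out.attrs["n_down"] = int(down.sum())
    out.attrs["n_ns"] = int(len(out) - up.sum() - down.sum())
    out.attrs["logfc_threshold"] = logfc_threshold
    out.attrs["alpha"] = alpha
    return out


def volcano_table(de: pd.DataFrame) -> pd.DataFrame:
    """(log2_fc, -log10 adjusted p) pairs for volcano plotting."""
    with np.errstate(divide="ignore"):
        neglog = -np.log10(de["adj_p"].to_numpy(dtype=float))
    return pd.DataFrame(
        {"log2_fc": de["log2_fc"], "neg_log10_adj_p": neglog, "class": de["class"]},
        index=de.index,
    )
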