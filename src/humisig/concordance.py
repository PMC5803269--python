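"""Transcriptome-proteome concordance: signature overlap and rank correlation.

Compares a protein quantification table (iBAQ-like relative abundances) with
the transcriptome: how many detected proteins belong to the derived gene
signature, and how strongly protein abundance rank-correlates with mean mRNA
expression over the matched genes (Spearman, average ranks for ties,
t-approximation p-value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exprio import ExpressionMatrix


@dataclass
class OverlapResult:
    count: int
    genes: list[str]
    unmapped: list[str] = field(default_factory=list)


def _map_ids(ids, mapping: dict | None) -> tuple[dict, list[str]]:
    """Apply an optional protein->gene mapping; identity where absent."""
    mapped, unmapped = {}, []
    for pid in ids:
        if mapping is None:
            mapped[pid] = pid
        elif pid in mapping:
            mapped[pid] = mapping[pid]
        else:
            unmapped.append(pid)
    return mapped, unmapped


def signature_overlap(
    proteins: pd.Series,
    signature,
    mapping: dict | None = None,
) -> OverlapResult:
    """Exact intersection of detected proteins with a gene signature.

    ``proteins`` is an abundance Series indexed by protein/gene identifier;
    ``mapping`` (protein id -> gene id) translates namespaces when given.
    Identifiers that cannot be mapped are reported, not silently dropped.
    """
    if proteins.index.has_duplicates:
        raise ValueError("protein table has duplicate identifiers")
    if (proteins.to_numpy(dtype=float) < 0).any():
        raise ValueError("protein abundances must be nonnegative")
    mapped, unmapped = _map_ids(proteins.index, mapping)
    genes = sorted(set(mapped.values()) & set(signature))
    return OverlapResult(count=len(genes), genes=genes, unmapped=unmapped)


def rank_correlation(
    proteins: pd.Series,
    m: ExpressionMatrix,
    mapping: dict | None = None,
    summary: str = "mean",
) -> tuple[float, float, int]:
    """Spearman correlation of protein abundance with summarized mRNA expression.

    mRNA is summarized per gene as the mean (or median) log2 value over the
    matrix's samples; raw-scale matrices are log2(x+1)-transformed first.
    Requires at least 3 matched identifiers. Returns (rho, p, n_matched).
    """
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    mapped, _ = _map_ids(proteins.index, mapping)
    vals = m.values.to_numpy(dtype=float)
    if m.scale == "raw":
        vals = np.log2(vals + 1.0)
    summarized = pd.Series(
        vals.mean(axis=1) if summary == "mean" else np.median(vals, axis=1),
        index=m.gene_ids,
    )
    pairs = [
        (float(proteins[pid]), float(summarized[gene]))
        for pid, gene in mapped.items()
        if gene in summarized.index
    ]
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} matched identifiers; need >= 3")
    prot, mrna = zip(*pairs)
    rho, p = stats.spearmanr(prot, mrna)
    return float(rho), float(p), len(pairs)
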