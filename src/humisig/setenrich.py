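"""Gene-set statistics: hypergeometric over-representation and pre-ranked GSEA.

Over-representation asks whether a signature overlaps a disease gene set
more than chance within a stated gene universe, via the exact upper-tail
hypergeometric probability P(X >= k). Pre-ranked GSEA measures whether a
gene set concentrates toward either end of a score-ranked gene list using
the weighted Kolmogorov-Smirnov running-sum statistic (ES), with a
gene-label permutation null providing the normalized score (NES) and a
signed permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def hypergeometric_ora(
    signature,
    disease_sets: dict,
    universe,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per disease set.

    The signature and each disease set are intersected with the universe;
    for each set the exact probability of observing an overlap at least as
    large as the one seen is computed: with N = |universe|, K = |set in
    universe|, n = |signature in universe|, k = |overlap|,
    p = P(X >= k) for X ~ Hypergeometric(N, K, n). One-sided (enrichment)
    only. Results are sorted by p-value.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    sig = set(signature) & universe
    if not sig:
        raise ValueError("signature is empty after intersection with universe")
    N, n = len(universe), len(sig)
    rows = []
    for name, genes in disease_sets.items():
        genes_u = set(genes) & universe
        K = len(genes_u)
        k = len(genes_u & sig)
        # sf(k-1) = P(X >= k); exact tail, p = 1 at k = 0
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set_name": name,
                "universe_size": N,
                "set_size_in_universe": K,
                "signature_size_in_universe": n,
                "overlap": k,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


@dataclass
class GseaResult:
    """Pre-ranked GSEA outcome for one gene set."""

    set_name: str
    es: float
    nes: float
    perm_p: float
    n_perm: int
    n_hits: int
    running_sum: np.ndarray  # deviation profile along the ranked list


def _enrichment_score(scores: np.ndarray, hits: np.ndarray, weight: float) -> tuple[float, np.ndarray]:
    """Signed maximum deviation of the weighted KS running sum.

    At hit positions the sum rises by |score|^weight / sum over hits of
    |score|^weight; at misses it falls by 1/(N - n_hits). If every hit score
    is zero under a positive weight, hits fall back to equal increments.
    """
    n = scores.size
    n_hits = int(hits.sum())
    hit_w = np.abs(scores) ** weight if weight != 0 else np.ones(n)
    hit_w = np.where(hits, hit_w, 0.0)
    total = hit_w.sum()
    if total <= 0:
        hit_w = hits.astype(float)
        total = hit_w.sum()
    incr = hit_w / total
    miss = 1.0 / (n - n_hits)
    running = np.cumsum(incr - np.where(hits, 0.0, miss))
    # earliest position wins |running| ties (1e-12 margin absorbs rounding)
    absr = np.abs(running)
    i = int(np.argmax(absr >= absr.max() - 1e-12))
    return float(running[i]), running


def preranked_gsea(
    ranked: pd.Series,
    gene_set,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    set_name: str = "gene_set",
) -> GseaResult:
    """Pre-ranked GSEA of ``gene_set`` against an ordered, scored gene list.

    ``ranked`` is a Series of scores indexed by unique gene ids, already in
    rank order (highest-scoring first by convention; the given order is
    authoritative and ties keep their input positions). The null is formed
    by permuting gene labels: each permutation re-assigns the set to random
    positions of the list. NES is ES divided by the mean |null ES| of the
    same sign; the permutation p is (1 + #{same-sign nulls at least as
    extreme}) / (#same-sign nulls + 1).
    """
    if ranked.index.has_duplicates:
        raise ValueError("ranked list contains duplicate genes")
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    hits = np.isin(genes, list(gene_set))
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if n_hits == genes.size:
        raise ValueError("gene set covers the entire ranked list")

    es, running = _enrichment_score(scores, hits, weight_exponent)

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    n = genes.size
    for b in range(n_perm):
        perm_hits = np.zeros(n, dtype=bool)
        perm_hits[rng.choice(n, size=n_hits, replace=False)] = True
        null_es[b], _ = _enrichment_score(scores, perm_hits, weight_exponent)

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same:
        nes = es / float(np.abs(null_es[same_sign]).mean())
        n_extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
    else:
        nes = float("nan")
        n_extreme = 0
    perm_p = (1.0 + n_extreme) / (n_same + 1.0)
    return GseaResult(
        set_name=set_name,
        es=es,
        nes=float(nes),
        perm_p=float(perm_p),
        n_perm=n_perm,
        n_hits=n_hits,
        running_sum=running,
    )


def rank_genes(scores: pd.Series, descending: bool = True) -> pd.Series:
    """Stable sort of a score vector into a ranked list (ties keep input order)."""
    order = np.argsort(-scores.to_numpy() if descending else scores.to_numpy(),
                       kind="mergesort")
    return scores.iloc[order]
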