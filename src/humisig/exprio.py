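"""Expression-matrix containers, file formats, and preprocessing.

Covers reading/writing of gene x sample expression matrices (TSV and GCT
v1.2), gene annotations, gene-set collections (GMT), and per-sample trait
tables, together with the preprocessing steps applied before signature
derivation: low-expression filtering (FPKM < threshold in more than
``max_low_samples`` samples), log2 transformation, filtering to genes with a
UniProt identifier, and a mean-variance precision-weight trend in the style
of voom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

VALID_SCALES = ("raw", "log2", "normalized")

ANNOTATION_COLUMNS = ["symbol", "gc_fraction", "length_bp", "has_uniprot"]


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with a scale tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. On the
        ``raw`` scale the entries are nonnegative FPKM-like abundances; on
        ``log2`` / ``normalized`` scales they may be any real number.
    scale
        One of ``raw``, ``log2``, ``normalized``.
    """

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if self.scale == "raw" and (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("raw-scale expression values must be nonnegative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in the order given)."""
        return ExpressionMatrix(self.values.loc[list(genes)], scale=self.scale)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_tsv(path, scale: str = "raw") -> ExpressionMatrix:
    """Read a TSV with genes as rows and a header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, scale=scale)


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def read_gct(path) -> ExpressionMatrix:
    """Read a GCT v1.2 file (two header lines, Name/Description columns)."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2",):
            raise ValueError(f"unsupported GCT version line {version!r}")
        dims = fh.readline().split()
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"])
    if df.shape != (n_genes, n_samples):
        raise ValueError(
            f"GCT header declares {n_genes}x{n_samples} but table is {df.shape}"
        )
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return ExpressionMatrix(df, scale="raw")


def write_gct(m: ExpressionMatrix, path, descriptions=None) -> None:
    df = m.values.copy()
    desc = (
        pd.Series(descriptions).reindex(df.index).fillna("na")
        if descriptions is not None
        else pd.Series("na", index=df.index)
    )
    out = df.copy()
    out.insert(0, "Description", desc)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{m.n_genes}\t{m.n_samples}\n")
        out.to_csv(fh, sep="\t", index_label="Name")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = sorted(sets[name])
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV: gene_id, symbol, gc_fraction, length_bp, has_uniprot.

    Validates one row per gene, GC fraction in [0, 1], and positive length;
    offending rows are named in the error.
    """
    ann = pd.read_csv(path, sep="\t", index_col=0)
    ann.index = ann.index.astype(str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    if ann.index.has_duplicates:
        dup = ann.index[ann.index.duplicated()].unique().tolist()
        raise ValueError(f"annotation has duplicate gene ids: {dup[:5]}")
    bad_gc = ann.index[(ann["gc_fraction"] < 0) | (ann["gc_fraction"] > 1)].tolist()
    if bad_gc:
        raise ValueError(f"gc_fraction outside [0,1] for genes {bad_gc[:5]}")
    bad_len = ann.index[ann["length_bp"] <= 0].tolist()
    if bad_len:
        raise ValueError(f"non-positive length_bp for genes {bad_len[:5]}")
    ann["has_uniprot"] = ann["has_uniprot"].astype(bool)
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="gene_id")


def read_traits(path) -> pd.DataFrame:
    """Read a per-sample trait table TSV indexed by sample id."""
    traits = pd.read_csv(path, sep="\t", index_col=0)
    traits.index = traits.index.astype(str)
    if traits.index.has_duplicates:
        dup = traits.index[traits.index.duplicated()].unique().tolist()
        raise ValueError(f"trait table has duplicate sample ids: {dup[:5]}")
    return traits


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_low_expression(
    m: ExpressionMatrix, threshold: float = 0.1, max_low_samples: int = 2
) -> ExpressionMatrix:
    """Drop genes with abundance below ``threshold`` in more than ``max_low_samples`` samples.

    A gene is kept iff the number of samples with value < threshold is at
    most ``max_low_samples``. Sample set and gene order are preserved.
    """
    if m.scale != "raw":
        raise ValueError(f"low-expression filter requires raw scale, got {m.scale!r}")
    n_low = (m.values < threshold).sum(axis=1)
    keep = n_low <= max_low_samples
    return ExpressionMatrix(m.values.loc[keep], scale="raw")


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); requires raw (nonnegative) input."""
    if m.scale != "raw":
        raise ValueError(f"log transform requires raw scale, got {m.scale!r}")
    vals = m.values.to_numpy(dtype=float)
    if (vals + pseudocount <= 0).any():
        raise ValueError("log transform undefined: value + pseudocount <= 0")
    out = pd.DataFrame(
        np.log2(vals + pseudocount), index=m.gene_ids, columns=m.sample_ids
    )
    return ExpressionMatrix(out, scale="log2")


def uniprot_filter(m: ExpressionMatrix, ann: pd.DataFrame) -> ExpressionMatrix:
    """Keep only genes flagged ``has_uniprot`` in the annotation.

    Genes absent from the annotation are treated as lacking a UniProt
    identifier and dropped (conservative exclusion). Gene order preserved.
    """
    flags = ann["has_uniprot"].reindex(m.gene_ids, fill_value=False).astype(bool)
    return ExpressionMatrix(m.values.loc[flags.to_numpy()], scale=m.scale)


def mean_variance_weights(m: ExpressionMatrix, span: float = 0.5) -> pd.DataFrame:
    """Precision weights from a lowess trend of sqrt-sd versus mean log expression.

    For each gene the across-sample mean and the square root of the standard
    deviation are computed; a lowess curve (``span`` fraction) is fit to
    sqrt-sd as a function of the mean, and each observation's weight is the
    inverse fourth power of the predicted sqrt-sd at its gene's mean. This is
    a deliberately simplified mean-variance weighting in the spirit of voom:
    the trend is evaluated at the gene mean rather than at per-observation
    fitted values, and no library-size model is involved. Weights are
    strictly positive.
    """
    if m.scale not in ("log2", "normalized"):
        raise ValueError("mean-variance trend requires a log-scale matrix")
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples to fit the mean-variance trend")
    means = m.values.mean(axis=1).to_numpy()
    sds = m.values.std(axis=1, ddof=1).to_numpy()
    sqrt_sd = np.sqrt(sds)
    fit = lowess(sqrt_sd, means, frac=span, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]
    predicted = np.interp(means, xs, ys)
    # sqrt-sd can be fit below zero at the extremes; floor keeps weights finite
    floor = max(1e-6, 0.01 * float(np.median(sqrt_sd[sqrt_sd > 0]) if (sqrt_sd > 0).any() else 1.0))
    predicted = np.maximum(predicted, floor)
    w = 1.0 / predicted**4
    weights = pd.DataFrame(
        np.repeat(w[:, None], m.n_samples, axis=1),
        index=m.gene_ids,
        columns=m.sample_ids,
    )
    return weights


def mean_variance_trend(m: ExpressionMatrix, grid: np.ndarray, span: float = 0.5) -> np.ndarray:
    """Evaluate the fitted sqrt-sd trend on ``grid`` (helper for diagnostics)."""
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples to fit the mean-variance trend")
    means = m.values.mean(axis=1).to_numpy()
    sqrt_sd = np.sqrt(m.values.std(axis=1, ddof=1).to_numpy())
    fit = lowess(sqrt_sd, means, frac=span, return_sorted=True)
    return np.interp(np.asarray(grid, dtype=float), fit[:, 0], fit[:, 1])
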