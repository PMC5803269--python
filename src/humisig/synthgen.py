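"""Synthetic purified-cell / bulk-mixture expression data with known truth.

Emulates the statistical structure of a purified-microglia vs bulk-cortex
study: bulk tissue is a mixture of a few cell types in which microglia are a
~12% minority, each cell type carries planted marker genes with a large
expression ratio, measurements carry GC-content and gene-length technical
biases plus lognormal noise, clinical traits correlate with the microglial
program, and disease gene sets share a planted overlap with the microglia
markers. Every generated object is accompanied by its ground truth so that
downstream recovery can be quantified.

All randomness flows through explicit integer seeds; there is no hidden
global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exprio import ExpressionMatrix

MICROGLIA = "microglia"


@dataclass
class MixtureDesign:
    """Parameters of the synthetic study.

    Defaults are the study conditions emulated throughout: 3 cell types with
    50 planted markers each at a log2 effect of 4, bulk tissue of 540 samples
    with a mean microglia fraction of 0.12, and 10 purified microglia
    replicates.

    Attributes
    ----------
    n_cell_types, n_genes, markers_per_type
        Counts; ``markers_per_type * n_cell_types`` must not exceed
        ``n_genes``.
    marker_log2_effect
        log2 expression ratio of a marker in its own cell type vs all others.
    mean_microglia_fraction
        Mean mixing proportion of microglia in bulk, in (0, 1).
    fraction_dispersion
        Dirichlet concentration for per-sample mixing-proportion noise
        (larger = tighter around the mean).
    noise_sd
        Standard deviation of measurement noise on the log2 scale
        (lognormal on the linear scale).
    gc_artifact_coef, length_artifact_coef
        Slopes of the planted log2-scale technical bias on centred GC
        fraction and centred log10 gene length, applied to bulk samples.
    n_bulk_samples, n_purified_replicates
        Sample counts of the two generated datasets.
    baseline_log2_mean, baseline_log2_sd
        Distribution of per-gene baseline log2 expression.
    n_aging_genes, aging_log2_effect
        Planted aging program used when generating a middle-aged comparison
        dataset: half the genes go up with age, half down, at the given
        log2 effect.
    """

    n_cell_types: int = 3
    n_genes: int = 2000
    markers_per_type: int = 50
    marker_log2_effect: float = 4.0
    mean_microglia_fraction: float = 0.12
    fraction_dispersion: float = 200.0
    noise_sd: float = 0.25
    gc_artifact_coef: float = 0.5
    length_artifact_coef: float = 0.2
    seed: int = 0
    n_bulk_samples: int = 540
    n_purified_replicates: int = 10
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    n_aging_genes: int = 100
    aging_log2_effect: float = 3.0

    def __post_init__(self) -> None:
        for name in ("n_cell_types", "n_genes", "markers_per_type",
                     "n_bulk_samples", "n_purified_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.mean_microglia_fraction < 1.0:
            raise ValueError("mean_microglia_fraction must lie in (0, 1)")
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError(
                "invalid design: markers_per_type * n_cell_types exceeds n_genes"
            )
        if self.noise_sd < 0 or self.fraction_dispersion <= 0:
            raise ValueError("noise_sd must be >= 0 and fraction_dispersion > 0")

    @property
    def cell_types(self) -> list[str]:
        return [MICROGLIA] + [f"other_{i}" for i in range(1, self.n_cell_types)]


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic run, for recovery testing."""

    marker_sets: dict[str, set[str]]
    proportions: pd.DataFrame | None = None
    trait_effects: dict[str, float] = field(default_factory=dict)
    disease_overlap_counts: dict[str, int] = field(default_factory=dict)
    aging_up_genes: set[str] = field(default_factory=set)
    aging_down_genes: set[str] = field(default_factory=set)

    def to_json_dict(self) -> dict:
        d = {
            "marker_sets": {k: sorted(v) for k, v in self.marker_sets.items()},
            "trait_effects": dict(self.trait_effects),
            "disease_overlap_counts": dict(self.disease_overlap_counts),
            "aging_up_genes": sorted(self.aging_up_genes),
            "aging_down_genes": sorted(self.aging_down_genes),
        }
        if self.proportions is not None:
            d["proportions"] = {
                s: [float(x) for x in row]
                for s, row in self.proportions.iterrows()
            }
        return d


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_annotation(design: MixtureDesign, uniprot_fraction: float = 0.95) -> pd.DataFrame:
    """Per-gene GC fraction, length and UniProt flag.

    GC ~ Uniform(0.3, 0.7); length log-uniform on [500, 100000] bp; a
    ``uniprot_fraction`` share of genes carries a UniProt identifier.
    Deterministic given the design seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 101]))
    genes = _gene_ids(design.n_genes)
    gc = rng.uniform(0.3, 0.7, size=design.n_genes)
    length = np.exp(rng.uniform(np.log(500.0), np.log(100000.0), size=design.n_genes))
    has_uniprot = rng.random(design.n_genes) < uniprot_fraction
    return pd.DataFrame(
        {
            "symbol": genes,
            "gc_fraction": gc,
            "length_bp": length.astype(int),
            "has_uniprot": has_uniprot,
        },
        index=pd.Index(genes, name="gene_id"),
    )


def generate_profiles(design: MixtureDesign) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Cell-type x gene base expression profiles with planted markers.

    Each cell type receives exactly ``markers_per_type`` marker genes (sets
    pairwise disjoint) whose base expression in their own type exceeds every
    other type's by ``marker_log2_effect`` on the log2 scale. Profiles are
    linear-scale (FPKM-like) values.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 202]))
    genes = _gene_ids(design.n_genes)
    base_log2 = rng.normal(design.baseline_log2_mean, design.baseline_log2_sd,
                           size=design.n_genes)
    marker_idx = rng.choice(
        design.n_genes,
        size=design.markers_per_type * design.n_cell_types,
        replace=False,
    )
    profiles_log2 = np.tile(base_log2, (design.n_cell_types, 1))
    marker_sets: dict[str, set[str]] = {}
    for t, ct in enumerate(design.cell_types):
        idx = marker_idx[t * design.markers_per_type:(t + 1) * design.markers_per_type]
        profiles_log2[t, idx] += design.marker_log2_effect
        marker_sets[ct] = {genes[i] for i in idx}
    profiles = pd.DataFrame(
        np.exp2(profiles_log2), index=design.cell_types, columns=genes
    )
    return profiles, SyntheticTruth(marker_sets=marker_sets)


def _dirichlet_alpha(design: MixtureDesign) -> np.ndarray:
    mean = np.full(design.n_cell_types, 0.0)
    mean[0] = design.mean_microglia_fraction
    if design.n_cell_types > 1:
        mean[1:] = (1.0 - design.mean_microglia_fraction) / (design.n_cell_types - 1)
    else:
        mean[0] = 1.0
    return design.fraction_dispersion * mean


def _artifact_log2(design: MixtureDesign, annotation: pd.DataFrame) -> np.ndarray:
    """Planted log2 bias as a function of centred GC and centred log10 length."""
    gc = annotation["gc_fraction"].to_numpy(dtype=float)
    loglen = np.log10(annotation["length_bp"].to_numpy(dtype=float))
    return (design.gc_artifact_coef * (gc - gc.mean())
            + design.length_artifact_coef * (loglen - loglen.mean()))


def generate_bulk(
    profiles: pd.DataFrame,
    design: MixtureDesign,
    annotation: pd.DataFrame | None = None,
    n_samples: int | None = None,
    truth: SyntheticTruth | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Bulk-tissue mixtures of the cell-type profiles.

    bulk[g, s] = (sum_t p[s, t] * profile[t, g]) * 2**artifact(gc_g, len_g)
                 * 2**N(0, noise_sd), with per-sample proportions p drawn
    from a Dirichlet centred on the design's mixing means. The GC/length
    artifact is applied to bulk samples only, emulating a dataset-level
    technical bias relative to the purified data.

    Returns the bulk matrix (genes x samples, raw scale) and the samples x
    cell-types proportion table; proportions are recorded in ``truth`` when
    given.
    """
    if n_samples is None:
        n_samples = design.n_bulk_samples
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 303]))
    alpha = _dirichlet_alpha(design)
    props = rng.dirichlet(alpha, size=n_samples)
    samples = [f"bulk_{i:03d}" for i in range(1, n_samples + 1)]
    proportions = pd.DataFrame(props, index=samples, columns=profiles.index)

    mixture = props @ profiles.to_numpy()  # samples x genes
    values = mixture.T  # genes x samples
    if annotation is not None:
        art = _artifact_log2(design, annotation.loc[profiles.columns])
        values = values * np.exp2(art)[:, None]
    if design.noise_sd > 0:
        values = values * np.exp2(
            rng.normal(0.0, design.noise_sd, size=values.shape)
        )
    bulk = ExpressionMatrix(
        pd.DataFrame(values, index=profiles.columns, columns=samples), scale="raw"
    )
    if truth is not None:
        truth.proportions = proportions
    return bulk, proportions


def generate_purified(
    profiles: pd.DataFrame,
    design: MixtureDesign,
    cell_type: str = MICROGLIA,
    n_replicates: int | None = None,
    annotation: pd.DataFrame | None = None,
    apply_artifact: bool = False,
) -> ExpressionMatrix:
    """Replicate measurements of one cell type's profile plus noise.

    The GC/length artifact model can optionally be applied (off by default:
    the purified dataset acts as the artifact-free reference).
    """
    if cell_type not in profiles.index:
        raise ValueError(f"unknown cell type {cell_type!r}")
    if n_replicates is None:
        n_replicates = design.n_purified_replicates
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 404]))
    base = profiles.loc[cell_type].to_numpy(dtype=float)
    values = np.tile(base[:, None], (1, n_replicates))
    if apply_artifact and annotation is not None:
        art = _artifact_log2(design, annotation.loc[profiles.columns])
        values = values * np.exp2(art)[:, None]
    if design.noise_sd > 0:
        values = values * np.exp2(rng.normal(0.0, design.noise_sd, size=values.shape))
    samples = [f"{cell_type}_{i:02d}" for i in range(1, n_replicates + 1)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=profiles.columns, columns=samples), scale="raw"
    )


def generate_middle_aged(
    profiles: pd.DataFrame,
    design: MixtureDesign,
    truth: SyntheticTruth,
    n_replicates: int = 3,
) -> ExpressionMatrix:
    """Synthetic middle-aged microglia dataset with a planted aging program.

    Starting from the microglia profile, ``n_aging_genes`` genes are planted:
    half are up-regulated with aging (their middle-aged expression is divided
    by 2**aging_log2_effect) and half down-regulated (multiplied). Replicates
    get the same lognormal noise model. The planted sets are recorded in the
    truth; a differential-expression contrast of aged vs this dataset should
    recover them.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 505]))
    genes = list(profiles.columns)
    n_aging = min(design.n_aging_genes, len(genes))
    idx = rng.choice(len(genes), size=n_aging, replace=False)
    half = n_aging // 2
    up = {genes[i] for i in idx[:half]}
    down = {genes[i] for i in idx[half:]}
    base = profiles.loc[MICROGLIA].copy()
    base[list(up)] /= 2.0**design.aging_log2_effect
    base[list(down)] *= 2.0**design.aging_log2_effect
    values = np.tile(base.to_numpy()[:, None], (1, n_replicates))
    if design.noise_sd > 0:
        values = values * np.exp2(rng.normal(0.0, design.noise_sd, size=values.shape))
    samples = [f"middle_{i:02d}" for i in range(1, n_replicates + 1)]
    truth.aging_up_genes = up
    truth.aging_down_genes = down
    return ExpressionMatrix(
        pd.DataFrame(values, index=profiles.columns, columns=samples), scale="raw"
    )


DEFAULT_TRAIT_EFFECTS: dict[str, float] = {
    # generative slope of each trait (or its latent) on the standardized
    # microglial program; signs follow the emulated biology: the microglial
    # signature rises with age and amyloid, falls with APOE e2, and is
    # unrelated to APOE e4, clinical diagnosis and tau
    "age_at_death": 3.0,
    "sex": 0.4,
    "clinical_AD": 0.0,
    "global_pathology": 0.0,
    "amyloid_load": 0.4,
    "tau_tangle_density": 0.0,
    "apoe_e2_count": -0.5,
    "apoe_e4_count": 0.0,
}

_TRAIT_SCALES: dict[str, tuple[float, float]] = {
    # (intercept, residual sd) of continuous traits / latents
    "age_at_death": (88.0, 5.0),
    "sex": (0.0, 1.0),
    "clinical_AD": (0.0, 1.0),
    "global_pathology": (0.5, 1.0),
    "amyloid_load": (1.0, 1.0),
    "tau_tangle_density": (1.0, 1.0),
    "apoe_e2_count": (0.0, 1.0),
    "apoe_e4_count": (0.0, 1.0),
}

# latent -> dosage thresholds chosen so allele frequencies are plausible
# (e2 ~ 8%, e4 ~ 14% under rough Hardy-Weinberg)
_ALLELE_QUANTILES = {"apoe_e2_count": (0.85, 0.99), "apoe_e4_count": (0.74, 0.98)}
_BINARY_QUANTILES = {"sex": 0.5, "clinical_AD": 0.65}


def generate_traits(
    proportions: pd.DataFrame,
    trait_effects: dict[str, float] | None = None,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> pd.DataFrame:
    """Per-sample clinicopathological traits correlated with the microglial program.

    Each trait (or a latent variable, for binary and allele-count traits) is
    intercept + slope * program + gaussian noise, where program is the
    z-scored true microglia mixing proportion. Binary traits threshold the
    latent at a fixed quantile; APOE allele counts cut it into {0, 1, 2}
    dosages. Slopes are recorded in the truth.
    """
    if trait_effects is None:
        trait_effects = dict(DEFAULT_TRAIT_EFFECTS)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    prog = proportions[MICROGLIA].to_numpy(dtype=float)
    prog = (prog - prog.mean()) / prog.std(ddof=0)
    out = {}
    for trait, slope in trait_effects.items():
        intercept, resid_sd = _TRAIT_SCALES.get(trait, (0.0, 1.0))
        latent = intercept + slope * prog + rng.normal(0.0, resid_sd, size=len(prog))
        if trait in _ALLELE_QUANTILES:
            q1, q2 = np.quantile(latent, _ALLELE_QUANTILES[trait])
            out[trait] = np.digitize(latent, [q1, q2]).astype(int)
        elif trait in _BINARY_QUANTILES:
            out[trait] = (latent > np.quantile(latent, _BINARY_QUANTILES[trait])).astype(int)
        else:
            out[trait] = latent
    traits = pd.DataFrame(out, index=proportions.index)
    if truth is not None:
        truth.trait_effects = dict(trait_effects)
    return traits


def generate_disease_sets(
    truth: SyntheticTruth,
    overlap_count: int,
    set_size: int,
    universe,
    seed: int = 0,
    name: str = "disease",
) -> dict[str, set[str]]:
    """A disease gene set with a planted overlap with the microglia markers.

    Exactly ``overlap_count`` genes are drawn from the microglia marker set
    and the remaining ``set_size - overlap_count`` from non-marker genes of
    the universe. Returned as a GMT-writable {name: genes} collection and
    recorded in the truth.
    """
    markers = sorted(truth.marker_sets[MICROGLIA] & set(universe))
    non_markers = sorted(set(universe) - truth.marker_sets[MICROGLIA])
    if overlap_count > min(set_size, len(markers)):
        raise ValueError(
            f"infeasible overlap: {overlap_count} > min(set_size={set_size}, "
            f"markers={len(markers)})"
        )
    if set_size - overlap_count > len(non_markers):
        raise ValueError("set_size exceeds available non-marker genes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 707]))
    chosen = set(rng.choice(markers, size=overlap_count, replace=False)) if overlap_count else set()
    chosen |= set(rng.choice(non_markers, size=set_size - overlap_count, replace=False))
    truth.disease_overlap_counts[name] = overlap_count
    return {name: {str(g) for g in chosen}}


def generate_protein_table(
    purified: ExpressionMatrix,
    truth: SyntheticTruth,
    n_proteins: int = 200,
    signature_genes: int = 30,
    log2_noise_sd: float = 2.5,
    seed: int = 0,
) -> pd.Series:
    """Synthetic shotgun-proteomics abundances for a subset of genes.

    Detection is biased toward abundant transcripts, a fixed number of
    microglia marker genes is forced into the detected list, and protein
    abundance is the mean mRNA log2 value plus heavy lognormal noise — so
    protein and transcript rank-correlate only moderately, as shotgun
    proteomes do.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 808]))
    mean_log2 = np.log2(purified.values.to_numpy(dtype=float) + 1.0).mean(axis=1)
    genes = purified.gene_ids.to_numpy()
    markers = sorted(truth.marker_sets[MICROGLIA] & set(genes))
    forced = list(rng.choice(markers, size=min(signature_genes, len(markers)),
                             replace=False))
    rest_pool = [g for g in genes if g not in set(forced)]
    pool_mean = pd.Series(mean_log2, index=genes).loc[rest_pool].to_numpy()
    w = np.exp(pool_mean - pool_mean.max())
    w /= w.sum()
    n_rest = min(n_proteins - len(forced), len(rest_pool))
    rest = list(rng.choice(rest_pool, size=n_rest, replace=False, p=w))
    detected = forced + rest
    det_mean = pd.Series(mean_log2, index=genes).loc[detected]
    abundance = np.exp2(det_mean.to_numpy()
                        + rng.normal(0.0, log2_noise_sd, size=len(detected)))
    return pd.Series(abundance, index=pd.Index(detected, name="protein_id"),
                     name="ibaq").sort_index()
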