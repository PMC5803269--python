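"""End-to-end orchestration from a single config: synthetic or file inputs.

Stage order: low-expression filter -> log2 -> UniProt filter -> residual
GC/length normalization -> purified-vs-bulk signature -> gene-set statistics
(ORA, pre-ranked GSEA) -> meta-feature trait associations -> aged vs
middle-aged differential expression -> proteome concordance. Every
stochastic stage takes an explicit seed through the config; a manifest
recording all applied parameters is written next to the outputs, and
re-running the same config reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agingde as agingde_mod
from . import concordance as concordance_mod
from . import exprio, metafeature, setenrich, signature, synthgen

logger = logging.getLogger("humisig")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class StageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All inputs and stage parameters of one pipeline run.

    With ``mode='synthetic'`` the design parameters drive the generator;
    with ``mode='files'`` the path fields name the TSV/GMT inputs. Stages
    whose inputs are absent (traits, disease sets, middle-aged dataset,
    proteins) are skipped with a logged warning.
    """

    mode: str = "synthetic"
    outdir: str = "humisig_run"
    seed: int = 0
    design: dict = field(default_factory=dict)
    # file-mode inputs
    purified_path: str | None = None
    bulk_path: str | None = None
    annotation_path: str | None = None
    traits_path: str | None = None
    disease_sets_path: str | None = None
    middle_aged_path: str | None = None
    proteins_path: str | None = None
    protein_mapping_path: str | None = None
    # stage parameters
    fpkm_threshold: float = 0.1
    max_low_samples: int = 2
    pseudocount: float = 1.0
    fc_threshold: float = 4.0
    alpha: float = 0.05
    gsea_weight: float = 1.0
    gsea_n_perm: int = 1000
    aging_logfc_threshold: float = 2.0
    aging_alpha: float = 0.05
    detect_threshold: float = 0.1
    min_detected_fraction: float = 0.5
    quantile_align: bool = True
    # synthetic extras
    disease_overlap_count: int = 20
    disease_set_size: int = 60
    n_null_disease_sets: int = 2
    n_proteins: int = 200

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise StageError(name, exc) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _json_dump(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass
class RunReport:
    """Structured summary of an end-to-end run."""

    signature_counts: dict
    ora_table: pd.DataFrame | None
    gsea_results: list
    association_table: pd.DataFrame | None
    de_counts: dict | None
    concordance: dict | None
    manifest: dict


@_stage("synthesize")
def _synthesize(config: RunConfig):
    design = synthgen.MixtureDesign(seed=config.seed, **config.design)
    ann = synthgen.generate_annotation(design)
    profiles, truth = synthgen.generate_profiles(design)
    bulk, proportions = synthgen.generate_bulk(profiles, design, ann, truth=truth)
    purified = synthgen.generate_purified(profiles, design)
    middle = synthgen.generate_middle_aged(profiles, design, truth)
    traits = synthgen.generate_traits(proportions, seed=design.seed, truth=truth)
    universe = list(profiles.columns)
    disease_sets = synthgen.generate_disease_sets(
        truth, config.disease_overlap_count, config.disease_set_size,
        universe, seed=design.seed, name="disease_enriched",
    )
    for i in range(config.n_null_disease_sets):
        disease_sets.update(
            synthgen.generate_disease_sets(
                truth, 0, config.disease_set_size, universe,
                seed=design.seed + 1 + i, name=f"disease_null_{i + 1}",
            )
        )
    proteins = synthgen.generate_protein_table(
        purified, truth, n_proteins=config.n_proteins, seed=design.seed
    )
    return {
        "purified": purified, "bulk": bulk, "annotation": ann,
        "traits": traits, "disease_sets": disease_sets,
        "middle_aged": middle, "proteins": proteins, "mapping": None,
        "truth": truth, "design": design,
    }


@_stage("load")
def _load(config: RunConfig):
    if not (config.purified_path and config.bulk_path and config.annotation_path):
        raise ValueError("file mode needs purified_path, bulk_path and annotation_path")
    data = {
        "purified": exprio.read_expression_tsv(config.purified_path),
        "bulk": exprio.read_expression_tsv(config.bulk_path),
        "annotation": exprio.read_annotation(config.annotation_path),
        "traits": None, "disease_sets": None, "middle_aged": None,
        "proteins": None, "mapping": None, "truth": None, "design": None,
    }
    if config.traits_path:
        data["traits"] = exprio.read_traits(config.traits_path)
    if config.disease_sets_path:
        data["disease_sets"] = exprio.read_gmt(config.disease_sets_path)
    if config.middle_aged_path:
        data["middle_aged"] = exprio.read_expression_tsv(config.middle_aged_path)
    if config.proteins_path:
        prot = pd.read_csv(config.proteins_path, sep="\t", index_col=0)
        data["proteins"] = prot.iloc[:, 0]
    if config.protein_mapping_path:
        mp = pd.read_csv(config.protein_mapping_path, sep="\t", index_col=0)
        data["mapping"] = mp.iloc[:, 0].to_dict()
    return data


@_stage("preprocess")
def _preprocess(config: RunConfig, matrix, ann):
    filtered = exprio.filter_low_expression(
        matrix, config.fpkm_threshold, config.max_low_samples
    )
    logged = exprio.log_transform(filtered, config.pseudocount)
    return exprio.uniprot_filter(logged, ann)


@_stage("signature")
def _signature_stage(config: RunConfig, purified, bulk, ann):
    common = purified.gene_ids.intersection(bulk.gene_ids)
    if len(common) == 0:
        raise ValueError("no shared genes between purified and bulk after filtering")
    keep = [g for g in purified.gene_ids if g in set(common)]
    combined = exprio.ExpressionMatrix(
        pd.concat([purified.values.loc[keep], bulk.values.loc[keep]], axis=1),
        scale="log2",
    )
    normalized, fit = signature.residual_normalize(combined, ann)
    pur_n = normalized.subset_genes(keep)
    pur_n = exprio.ExpressionMatrix(
        pur_n.values[purified.sample_ids.tolist()], scale="normalized"
    )
    bulk_n = exprio.ExpressionMatrix(
        normalized.values[bulk.sample_ids.tolist()], scale="normalized"
    )
    lfc = signature.fold_change_contrast(pur_n, bulk_n)
    mod = signature.moderated_t(pur_n, bulk_n)
    sig = signature.derive_signature(lfc, mod, config.fc_threshold, config.alpha)
    return sig, fit, pur_n, bulk_n


@_stage("setenrich")
def _setenrich_stage(config: RunConfig, sig, disease_sets, universe):
    fc_set = set(sig.index[sig["in_fc_set"]])
    ora = setenrich.hypergeometric_ora(fc_set, disease_sets, universe)
    ranked = setenrich.rank_genes(sig["log2_fc"])
    gsea = []
    for name, genes in disease_sets.items():
        inset = set(genes) & set(ranked.index)
        if 0 < len(inset) < len(ranked):
            gsea.append(
                setenrich.preranked_gsea(
                    ranked, inset, config.gsea_weight, config.gsea_n_perm,
                    seed=config.seed, set_name=name,
                )
            )
    return ora, gsea


@_stage("metafeature")
def _metafeature_stage(sig, bulk_log, traits):
    fc_set = set(sig.index[sig["in_fc_set"]])
    score = metafeature.metafeature_score(bulk_log, fc_set)
    table = metafeature.associate_traits(score, traits)
    return score, table


@_stage("agingde")
def _agingde_stage(config: RunConfig, aged_raw, middle_raw):
    pair = agingde_mod.harmonize(
        aged_raw, middle_raw, config.detect_threshold,
        config.min_detected_fraction, config.quantile_align, config.pseudocount,
    )
    de = agingde_mod.differential_expression(
        pair, config.aging_logfc_threshold, config.aging_alpha
    )
    return de


@_stage("concordance")
def _concordance_stage(sig, proteins, purified_log, mapping):
    fc_set = set(sig.index[sig["in_fc_set"]])
    overlap = concordance_mod.signature_overlap(proteins, fc_set, mapping)
    rho, p, n = concordance_mod.rank_correlation(proteins, purified_log, mapping)
    return {
        "overlap_count": overlap.count,
        "overlap_genes": overlap.genes,
        "n_unmapped": len(overlap.unmapped),
        "spearman_rho": rho,
        "spearman_p": p,
        "n_matched": n,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage the config's inputs allow and write all outputs.

    Outputs under ``config.outdir``: signature.tsv + signature GMT, ORA and
    GSEA tables, the trait-association table (Table-1 layout), the aging DE
    table with volcano data, the concordance report, and manifest.json with
    every applied parameter. Deterministic given the config's seeds.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = _synthesize(config) if config.mode == "synthetic" else _load(config)

    pur_log = _preprocess(config, data["purified"], data["annotation"])
    bulk_log = _preprocess(config, data["bulk"], data["annotation"])

    sig, norm_fit, pur_n, bulk_n = _signature_stage(
        config, pur_log, bulk_log, data["annotation"]
    )
    sig_out = sig.copy()
    sig_out.to_csv(outdir / "signature.tsv", sep="\t", index_label="gene_id")
    fc_set = set(sig.index[sig["in_fc_set"]])
    pval_set = set(sig.index[sig["in_pval_set"]])
    exprio.write_gmt(
        {"signature_fc": fc_set, "signature_pval": pval_set},
        outdir / "signature_sets.gmt",
    )
    norm_fit.coefficients.to_csv(outdir / "artifact_fit.tsv", sep="\t",
                                 index_label="sample_id")

    universe = set(sig.index)
    ora_table, gsea_results = None, []
    if not fc_set:
        logger.warning("signature FC set is empty; enrichment and trait stages skipped")
        data = {**data, "disease_sets": None, "traits": None}
    if data["disease_sets"]:
        ora_table, gsea_results = _setenrich_stage(
            config, sig, data["disease_sets"], universe
        )
        ora_table.to_csv(outdir / "ora.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"set_name": g.set_name, "es": g.es, "nes": g.nes,
                 "perm_p": g.perm_p, "n_perm": g.n_perm, "n_hits": g.n_hits}
                for g in gsea_results
            ]
        ).to_csv(outdir / "gsea.tsv", sep="\t", index=False)
    else:
        logger.warning("no disease gene sets provided; enrichment stage skipped")

    assoc_table, score = None, None
    if data["traits"] is not None:
        score, assoc_table = _metafeature_stage(sig, bulk_log, data["traits"])
        assoc_table.to_csv(outdir / "trait_associations.tsv", sep="\t", index=False)
        score.scores.to_csv(outdir / "metafeature_scores.tsv", sep="\t",
                            index_label="sample_id")
    else:
        logger.warning("no trait table provided; trait-association stage skipped")

    de_counts, de = None, None
    if data["middle_aged"] is not None:
        de = _agingde_stage(config, data["purified"], data["middle_aged"])
        de.to_csv(outdir / "aging_de.tsv", sep="\t", index_label="gene_id")
        agingde_mod.volcano_table(de).to_csv(outdir / "aging_volcano.tsv", sep="\t",
                                             index_label="gene_id")
        de_counts = {"up": de.attrs["n_up"], "down": de.attrs["n_down"],
                     "ns": de.attrs["n_ns"]}
    else:
        logger.warning("no middle-aged dataset provided; aging DE stage skipped")

    conc = None
    if data["proteins"] is not None:
        conc = _concordance_stage(sig, data["proteins"], pur_log, data["mapping"])
        _json_dump(conc, outdir / "concordance.json")
    else:
        logger.warning("no protein table provided; concordance stage skipped")

    manifest = {
        "config": dataclasses.asdict(config),
        "n_genes_tested": int(len(sig)),
        "signature_counts": {"fc_set": sig.attrs["n_fc_set"],
                             "pval_set": sig.attrs["n_pval_set"]},
        "stages_run": {
            "setenrich": ora_table is not None,
            "metafeature": assoc_table is not None,
            "agingde": de_counts is not None,
            "concordance": conc is not None,
        },
    }
    if data["truth"] is not None:
        _json_dump(data["truth"].to_json_dict(), outdir / "truth.json")
        manifest["synthetic_design"] = dataclasses.asdict(data["design"])
    _json_dump(manifest, outdir / "manifest.json")

    return RunReport(
        signature_counts=manifest["signature_counts"],
        ora_table=ora_table,
        gsea_results=gsea_results,
        association_table=assoc_table,
        de_counts=de_counts,
        concordance=conc,
        manifest=manifest,
    )
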