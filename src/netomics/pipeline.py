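"""End-to-end orchestration: synthetic cohorts -> differential calling ->
correlation networks -> SNF fusion -> community detection -> cross-cancer
consensus -> mutation profiling -> prognostic survival screen.

Every stage is a pure function of (inputs, parameters, seed); re-running a
config reproduces byte-identical tables.  Stage artifacts are checkpointed
under the output directory as plain-text tables so individual stages can be
inspected or re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .communities import (AnnotationCatalog, Partition, detect_communities,
                          evaluate_partitions)
from .consensus import co_membership_pairs, consensus_groups, mutation_profile
from .differential import (cpm, differential_expression, differential_methylation,
                           demg, gene_level_methylation, gene_methylation_direction,
                           pair_probes_with_genes, select_distal_probes)
from .fusion import SNFParams, snf_fuse
from .networks import correlation_network
from .survival import (PrognosticWeights, cancer_cutoffs, gene_level_cutoffs,
                       score_matrix, survival_records, survival_screen)
from .synthetic import (CANCER_TYPES, CohortConfig, MultiOmicsCohort, PlantedTruth,
                        default_cohort_config, generate_annotation, generate_cohort,
                        split_cohort)

logger = logging.getLogger(__name__)

STAGES = ("generate", "differential", "networks", "clustering", "consensus", "survival")


@dataclass
class PipelineConfig:
    """All stage parameters of the pipeline; defaults are the study settings
    (|log2FC| > 1.0, FDR < 0.05, 2 kb distal cutoff, sig.dif 0.3, adjusted
    p < 0.01, SNF K = 9 / t = 20, weights 0.5/0.3/0.2, HR > 1.0,
    p < 0.05)."""

    cancer_types: tuple = CANCER_TYPES
    cohort: CohortConfig = field(default_factory=default_cohort_config)
    split_fraction: float = 0.5
    lfc_threshold: float = 1.0
    de_fdr: float = 0.05
    min_dist: int = 2000
    sig_dif: float = 0.3
    dm_alpha: float = 0.01
    pair_alpha: float = 0.05
    n_up: int = 10
    n_down: int = 10
    snf: SNFParams = field(default_factory=SNFParams)
    methods: tuple = ("fastgreedy", "louvain", "infomap")
    bioscore_t: float = 0.05
    weights: PrognosticWeights = field(default_factory=PrognosticWeights)
    hr_min: float = 1.0
    p_max: float = 0.05
    keep_untreated_early: bool = True  # filter polarity; False drops them instead
    seed: int = 1
    outdir: str | None = None


def validate_config(config: PipelineConfig) -> list[str]:
    """Every config invariant checked; empty list iff valid."""
    v = []
    w = config.weights
    if abs(w.w_expr + w.w_meth + w.w_mut - 1.0) > 1e-9:
        v.append("weights must sum to 1")
    if min(w.w_expr, w.w_meth, w.w_mut) < 0:
        v.append("weights must be non-negative")
    if config.snf.K < 1:
        v.append("SNF K must be >= 1")
    if config.snf.t < 1:
        v.append("SNF t must be >= 1")
    if not (0 < config.split_fraction < 1):
        v.append("split_fraction must be in (0, 1)")
    if config.lfc_threshold <= 0:
        v.append("lfc_threshold must be positive")
    for name in ("de_fdr", "dm_alpha", "pair_alpha", "bioscore_t", "p_max"):
        x = getattr(config, name)
        if not (0 < x < 1):
            v.append(f"{name} must be in (0, 1)")
    if config.min_dist < 0:
        v.append("min_dist must be non-negative")
    if not (0 <= config.sig_dif <= 1):
        v.append("sig_dif must be in [0, 1]")
    if config.hr_min < 0:
        v.append("hr_min must be non-negative")
    if not set(config.methods) <= {"fastgreedy", "louvain", "infomap"}:
        v.append("unknown community-detection method")
    try:
        config.cohort.validate()
    except ValueError as exc:
        v.append(str(exc))
    return v


def filter_untreated_early(cohort: MultiOmicsCohort, keep: bool = True) -> MultiOmicsCohort:
    """Apply the clinical cohort filter on tumor samples.

    keep=True keeps untreated stage-I/II tumor patients (plus all normals);
    keep=False drops exactly those instead.
    """
    clin = cohort.clinical
    early = (~clin["treated"].astype(bool)) & clin["stage"].isin(["I", "II"])
    tumor = cohort.group == "tumor"
    if keep:
        mask = ~tumor | early
    else:
        mask = ~tumor | ~early
    return cohort.subset(list(cohort.clinical.index[mask]))


def synthetic_catalog(truth: PlantedTruth, all_genes: list[str], seed: int = 0,
                      n_noise_terms: int = 10) -> AnnotationCatalog:
    """Cancer-related GO-BP/KEGG catalog aligned with the planted modules.

    Each planted module contributes one cancer-related GO-BP and one KEGG
    term (its genes plus a few random extras); noise terms of random genes
    (half tagged cancer-related) pad the catalog.
    """
    rng = np.random.default_rng(seed)
    terms, source, cancer = {}, {}, {}
    for name, genes in truth.module_genes.items():
        extra = set(rng.choice(all_genes, size=5, replace=False))
        terms[f"GOBP_{name}"] = set(genes) | extra
        source[f"GOBP_{name}"] = "GO-BP"
        cancer[f"GOBP_{name}"] = True
        extra = set(rng.choice(all_genes, size=5, replace=False))
        terms[f"KEGG_{name}"] = set(genes) | extra
        source[f"KEGG_{name}"] = "KEGG"
        cancer[f"KEGG_{name}"] = True
    for i in range(n_noise_terms):
        t = f"NOISE_{i:02d}"
        terms[t] = set(rng.choice(all_genes, size=15, replace=False))
        source[t] = "GO-BP" if i % 2 == 0 else "KEGG"
        cancer[t] = i % 2 == 0
    return AnnotationCatalog(terms, source, cancer)


# ---------------------------------------------------------------------------
# per-dataset differential stage
# ---------------------------------------------------------------------------

@dataclass
class DatasetResult:
    """Differential results for one (cancer type, split) dataset."""

    cancer_type: str
    split: str
    de: pd.DataFrame
    dm: pd.DataFrame
    pairs: pd.DataFrame
    glm: pd.DataFrame
    demg_hypo: set
    demg_hyper: set

    def demg(self, direction: str) -> set:
        return self.demg_hypo if direction == "hypo" else self.demg_hyper

    def counts_summary(self) -> dict:
        return {
            "n_de": int(self.de["passes"].sum()),
            "n_dm_hypo": int((self.dm["passes"] & (self.dm["direction"] == "hypo")).sum()),
            "n_dm_hyper": int((self.dm["passes"] & (self.dm["direction"] == "hyper")).sum()),
            "n_pairs": int(self.pairs["significant"].sum()),
            "n_demg_hypo": len(self.demg_hypo),
            "n_demg_hyper": len(self.demg_hyper),
        }


def run_differential_stage(
    cohort: MultiOmicsCohort,
    annotation,
    manifest,
    config: PipelineConfig,
    split: str,
) -> DatasetResult:
    de = differential_expression(cohort.counts, cohort.group,
                                 config.lfc_threshold, config.de_fdr)
    distal = select_distal_probes(manifest, annotation, config.min_dist)
    betas_distal = cohort.betas.loc[cohort.betas.index.intersection(distal)]
    dm = differential_methylation(betas_distal, cohort.group, config.sig_dif, config.dm_alpha)
    log_expr = np.log2(cpm(cohort.counts) + 1.0)
    pairs = pair_probes_with_genes(dm, de, betas_distal, log_expr, annotation, manifest,
                                   config.n_up, config.n_down, config.pair_alpha)
    glm = gene_level_methylation(pairs, betas_distal)
    direction = gene_methylation_direction(pairs, dm)
    hypo, hyper = demg(de, glm, direction)
    return DatasetResult(cohort.cancer_type, split, de, dm, pairs, glm, hypo, hyper)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages for every cancer type and split; returns the run
    manifest (and writes artifacts when ``config.outdir`` is set)."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"seed": config.seed, "stages": [], "cancer_types": list(config.cancer_types)}
    if not config.cancer_types:
        manifest["note"] = "empty cancer list; nothing to do"
        return manifest

    # --- generate ----------------------------------------------------------
    annotation, probe_manifest = generate_annotation(
        config.cohort.n_genes, config.cohort.n_probes, seed=config.seed
    )
    cohorts: dict[str, MultiOmicsCohort] = {}
    truth: PlantedTruth | None = None
    for i, ct in enumerate(config.cancer_types):
        cfg = replace(config.cohort, seed=config.seed * 1000 + i)
        cohort, truth = generate_cohort(cfg, annotation, probe_manifest, cancer_type=ct)
        cohorts[ct] = filter_untreated_early(cohort, config.keep_untreated_early)
    manifest["stages"].append("generate")
    if outdir:
        nio.write_annotation_bed(annotation, outdir / "annotation.bed.tsv")
        nio.write_manifest(probe_manifest, outdir / "probe_manifest.tsv")
        nio.write_truth(truth, outdir / "planted_truth.json")

    catalog = synthetic_catalog(truth, annotation.gene_ids, seed=config.seed)
    if outdir:
        nio.write_gmt(catalog, outdir / "catalog.gmt")

    # --- differential ------------------------------------------------------
    splits: dict[str, dict[str, MultiOmicsCohort]] = {}
    datasets: dict[tuple[str, str], DatasetResult] = {}
    for ct in config.cancer_types:
        train, val = split_cohort(cohorts[ct], config.split_fraction, seed=config.seed + 17)
        splits[ct] = {"train": train, "validation": val}
        for split_name, sub in splits[ct].items():
            datasets[(ct, split_name)] = run_differential_stage(
                sub, annotation, probe_manifest, config, split_name
            )
    manifest["stages"].append("differential")
    manifest["differential"] = {
        f"{ct}_{sp}": datasets[(ct, sp)].counts_summary()
        for ct in config.cancer_types for sp in ("train", "validation")
    }

    # --- networks + clustering --------------------------------------------
    best_partitions: dict[tuple[str, str, str], Partition] = {}
    evaluations: dict[str, dict] = {}
    for (ct, sp), ds in datasets.items():
        sub = splits[ct][sp]
        tumor = [s for s in sub.samples if sub.group[s] == "tumor"]
        log_expr = np.log2(cpm(sub.counts) + 1.0)
        for direction in ("hypo", "hyper"):
            genes = sorted(ds.demg(direction))
            if len(genes) <= config.snf.K:
                logger.warning("%s %s %s: only %d DEMG genes (<= K); skipped",
                               ct, sp, direction, len(genes))
                continue
            net_e = correlation_network(log_expr.loc[genes, tumor])
            net_m = correlation_network(ds.glm.loc[genes, tumor])
            fused = snf_fuse(net_e, net_m, config.snf)
            parts = [detect_communities(fused, m, seed=config.seed) for m in config.methods]
            report = evaluate_partitions(parts, catalog, t=config.bioscore_t)
            best_method = report.index[report["best"]][0]
            best = next(p for p in parts if p.method == best_method)
            best_partitions[(ct, sp, direction)] = best
            evaluations[f"{ct}_{sp}_{direction}"] = report.drop(columns="best").to_dict("index")
            if outdir:
                nio.write_network_graphml(fused, outdir / f"fused_{ct}_{sp}_{direction}.graphml")
                nio.write_partition(best, outdir / f"partition_{ct}_{sp}_{direction}.tsv")
    manifest["stages"] += ["networks", "clustering"]
    manifest["evaluation"] = evaluations

    # --- consensus ---------------------------------------------------------
    consensus: dict[str, list] = {}
    biomarkers: dict[str, set] = {}
    for direction in ("hypo", "hyper"):
        keys = [(ct, sp, direction) for ct in config.cancer_types for sp in ("train", "validation")]
        if any(k not in best_partitions for k in keys):
            consensus[direction] = []
            biomarkers[direction] = set()
            continue
        universe = set.intersection(
            *[datasets[(ct, sp)].demg(direction) for ct, sp, _ in keys]
        )
        if not universe:
            consensus[direction] = []
            biomarkers[direction] = set()
            continue
        pair_sets = [co_membership_pairs(best_partitions[k], universe) for k in keys]
        groups, _singletons = consensus_groups(pair_sets, direction)
        consensus[direction] = [sorted(g.genes) for g in groups]
        biomarkers[direction] = set().union(*(g.genes for g in groups)) if groups else set()
    manifest["stages"].append("consensus")
    manifest["consensus"] = consensus
    if outdir:
        rows = [
            {"group": f"{d}_{i}", "direction": d, "genes": ",".join(genes)}
            for d in consensus for i, genes in enumerate(consensus[d])
        ]
        pd.DataFrame(rows, columns=["group", "direction", "genes"]).to_csv(
            outdir / "consensus_groups.tsv", sep="\t", index=False
        )

    # --- mutation profile --------------------------------------------------
    all_biomarkers = biomarkers["hypo"] | biomarkers["hyper"]
    mutation_profiles = {}
    for ct in config.cancer_types:
        cohort = cohorts[ct]
        tumor_clin = cohort.clinical[cohort.group == "tumor"]
        if all_biomarkers:
            prof = mutation_profile(cohort.mutations, all_biomarkers, tumor_clin,
                                    keep_untreated_early=True)
            mutation_profiles[ct] = prof
            if outdir:
                prof.to_csv(outdir / f"mutation_profile_{ct}.tsv", sep="\t")
    manifest["mutation_profile"] = {
        ct: {g: int(prof.loc[g, "n_patients_mutated"]) for g in prof.index}
        for ct, prof in mutation_profiles.items()
    }

    # --- survival ----------------------------------------------------------
    screens: dict[str, pd.DataFrame] = {}
    cutoff_table = []
    for ct in config.cancer_types:
        cohort = cohorts[ct]
        tumor = [s for s in cohort.samples if cohort.group[s] == "tumor"]
        records = survival_records(cohort.clinical.loc[tumor])
        train_ds = datasets[(ct, "train")]
        for direction in ("hypo", "hyper"):
            demg_common = sorted(
                datasets[(ct, "train")].demg(direction)
                & datasets[(ct, "validation")].demg(direction)
            )
            if not demg_common:
                continue
            glm_full = gene_level_methylation(train_ds.pairs, cohort.betas[tumor])
            sm = score_matrix(cohort.counts[tumor], glm_full, cohort.mutations,
                              demg_common, config.weights)
            per_gene = [gene_level_cutoffs(sm[g].values) for g in sm.columns]
            avg_high, avg_low = cancer_cutoffs(per_gene)
            cutoff_table.append({"cancer_type": ct, "direction": direction,
                                 "avg_low": avg_low, "avg_high": avg_high,
                                 "n_demg_common": len(demg_common)})
            screen = survival_screen(sm, records, config.hr_min, config.p_max,
                                     cutoffs=(avg_high, avg_low))
            screens[f"{ct}_{direction}"] = screen
            if outdir:
                screen.to_csv(outdir / f"screen_{ct}_{direction}.tsv", sep="\t", index=False)
    manifest["stages"].append("survival")
    manifest["cutoffs"] = cutoff_table
    manifest["screen_hits"] = {
        key: sorted(set(s["gene"])) for key, s in screens.items()
    }

    digest = hashlib.sha256(
        json.dumps(
            {k: manifest[k] for k in ("differential", "consensus", "screen_hits")},
            sort_keys=True,
        ).encode()
    ).hexdigest()
    manifest["result_hash"] = digest
    if outdir:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
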