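"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is tab-separated text (counts/betas/clinical/annotation/MAF-like
tables), GMT for gene-set catalogs, GraphML for fused networks and JSON for
planted truth and run manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .communities import AnnotationCatalog, Partition
from .networks import GeneNetwork
from .synthetic import GenomeAnnotation, MultiOmicsCohort, PlantedTruth, ProbeManifest


# ---------------------------------------------------------------------------
# matrices and tables
# ---------------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation_bed(annotation: GenomeAnnotation, path) -> None:
    """BED-like: chrom, start, end, gene_id, score, strand (TSS as a 1 bp
    interval)."""
    t = annotation.table
    bed = pd.DataFrame(
        {
            "chrom": t["chromosome"],
            "start": t["tss"],
            "end": t["tss"] + 1,
            "name": t["gene_id"],
            "score": 0,
            "strand": t["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_annotation_bed(path) -> GenomeAnnotation:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    return GenomeAnnotation(pd.DataFrame({
        "gene_id": bed["name"],
        "chromosome": bed["chrom"],
        "tss": bed["start"],
        "strand": bed["strand"],
    }))


def write_manifest(manifest: ProbeManifest, path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> ProbeManifest:
    return ProbeManifest(pd.read_csv(path, sep="\t"))


def write_cohort(cohort: MultiOmicsCohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.counts, outdir / "counts.tsv", "gene_id")
    write_matrix(cohort.betas, outdir / "betas.tsv", "probe_id")
    cohort.mutations.to_csv(outdir / "mutations.maf.tsv", sep="\t", index=False)
    clin = cohort.clinical.copy()
    clin["group"] = cohort.group
    clin.to_csv(outdir / "clinical.tsv", sep="\t", index_label="sample")


def read_cohort(outdir, cancer_type: str = "SYN") -> MultiOmicsCohort:
    outdir = Path(outdir)
    clin = pd.read_csv(outdir / "clinical.tsv", sep="\t", index_col="sample")
    group = clin.pop("group")
    return MultiOmicsCohort(
        counts=read_matrix(outdir / "counts.tsv"),
        betas=read_matrix(outdir / "betas.tsv"),
        mutations=pd.read_csv(outdir / "mutations.maf.tsv", sep="\t"),
        clinical=clin,
        group=group,
        cancer_type=cancer_type,
    )


def write_truth(truth: PlantedTruth, path) -> None:
    payload = {
        "de_genes": list(truth.de_genes),
        "dm_probes_hypo": list(truth.dm_probes_hypo),
        "dm_probes_hyper": list(truth.dm_probes_hyper),
        "module_genes": {k: list(v) for k, v in truth.module_genes.items()},
        "module_direction": dict(truth.module_direction),
        "prognostic_genes": dict(truth.prognostic_genes),
        "mutated_genes": list(truth.mutated_genes),
        "probe_gene": dict(truth.probe_gene),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> PlantedTruth:
    d = json.loads(Path(path).read_text())
    return PlantedTruth(
        de_genes=tuple(d["de_genes"]),
        dm_probes_hypo=tuple(d["dm_probes_hypo"]),
        dm_probes_hyper=tuple(d["dm_probes_hyper"]),
        module_genes={k: tuple(v) for k, v in d["module_genes"].items()},
        module_direction=d["module_direction"],
        prognostic_genes=d["prognostic_genes"],
        mutated_genes=tuple(d["mutated_genes"]),
        probe_gene=d["probe_gene"],
    )


# ---------------------------------------------------------------------------
# networks and partitions
# ---------------------------------------------------------------------------

def write_edge_list(network: GeneNetwork, path) -> None:
    rows = []
    n = len(network.genes)
    for i in range(n):
        for j in range(i + 1, n):
            w = network.weights[i, j]
            if w > 0:
                rows.append((network.genes[i], network.genes[j], w))
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(path, sep="\t", index=False)


def write_network_graphml(network: GeneNetwork, path) -> None:
    g = nx.Graph()
    g.add_nodes_from(network.genes)
    n = len(network.genes)
    for i in range(n):
        for j in range(i + 1, n):
            w = float(network.weights[i, j])
            if w > 0:
                g.add_edge(network.genes[i], network.genes[j], weight=w)
    nx.write_graphml(g, path)


def write_partition(partition: Partition, path) -> None:
    pd.DataFrame(
        sorted(partition.assignment.items()), columns=["gene", "module"]
    ).to_csv(path, sep="\t", index=False)


def read_partition(path, method: str = "unknown") -> Partition:
    df = pd.read_csv(path, sep="\t")
    return Partition(method, dict(zip(df["gene"], df["module"])))


# ---------------------------------------------------------------------------
# GMT catalogs
# ---------------------------------------------------------------------------

def write_gmt(catalog: AnnotationCatalog, path) -> None:
    """GMT lines: term <TAB> source|cancer-flag description <TAB> genes..."""
    with open(path, "w") as fh:
        for term, genes in catalog.terms.items():
            desc = f"{catalog.source[term]}|{'cancer' if catalog.cancer_related.get(term) else 'other'}"
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_gmt(path) -> AnnotationCatalog:
    terms, source, cancer = {}, {}, {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, desc, genes = parts[0], parts[1], parts[2:]
            src, _, flag = desc.partition("|")
            terms[term] = set(genes)
            source[term] = src or "GO-BP"
            cancer[term] = flag == "cancer"
    return AnnotationCatalog(terms, source, cancer)
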