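"""Community detection on fused gene networks and biological scoring.

Three community-detection algorithms (Fast Greedy and Louvain, both
modularity-based, and Infomap, which minimizes a random-walk description
length) are run on each fused network through python-igraph.  Partitions
are scored with two biological metrics:

* BHI (biological homogeneity index): the mean, over modules with at least
  two annotated genes, of the fraction of ordered pairs of distinct
  annotated genes sharing at least one functional class.
* Bioscore: a cancer-adapted cluster score.  For each module, every
  cancer-related term of a source (GO-BP or KEGG) is tested for
  over-representation with a one-sided hypergeometric (Fisher) test, BH
  adjusted within the module; each gene then scores the number of
  significant terms it belongs to, gene scores are summed per module, and
  module scores are min-max normalized across the partition's modules.

The best algorithm per dataset is the one with the highest average GO-BP
Bioscore, ties broken by average BHI and then method name.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import benjamini_hochberg
from .networks import GeneNetwork

logger = logging.getLogger(__name__)

METHODS = ("fastgreedy", "louvain", "infomap")


@dataclass(frozen=True)
class Partition:
    method: str
    assignment: dict  # gene -> module id (int)

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for g, m in self.assignment.items():
            out.setdefault(m, set()).add(g)
        return out


@dataclass(frozen=True)
class AnnotationCatalog:
    """Flat term -> gene-set catalog with a source and cancer-related tag."""

    terms: dict  # term id -> set of genes
    source: dict  # term id -> {"GO-BP", "KEGG"}
    cancer_related: dict  # term id -> bool

    def __post_init__(self):
        for t, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term '{t}' has an empty gene set")

    def cancer_terms(self, source: str) -> list[str]:
        return [t for t in self.terms
                if self.source[t] == source and self.cancer_related.get(t, False)]

    def gene_classes(self) -> dict[str, set[str]]:
        """gene -> set of all annotation classes (for BHI)."""
        out: dict[str, set[str]] = {}
        for t, genes in self.terms.items():
            for g in genes:
                out.setdefault(g, set()).add(t)
        return out


def _graph_from_network(network: GeneNetwork) -> ig.Graph:
    n = len(network.genes)
    iu = np.triu_indices(n, k=1)
    w = network.weights[iu]
    keep = w > 0
    edges = list(zip(iu[0][keep].tolist(), iu[1][keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = w[keep].tolist()
    g.vs["name"] = list(network.genes)
    return g


def detect_communities(network: GeneNetwork, method: str, seed: int = 0) -> Partition:
    """Run one community-detection algorithm on a weighted gene network.

    igraph draws randomness from Python's ``random`` module; seeding it
    makes Louvain and Infomap deterministic under ``seed``.
    """
    if len(network.genes) == 0:
        raise ValueError("empty network")
    if method not in METHODS:
        raise ValueError(f"unknown method '{method}'; expected one of {METHODS}")
    g = _graph_from_network(network)
    random.seed(seed)
    if method == "fastgreedy":
        clustering = g.community_fastgreedy(weights="weight").as_clustering()
    elif method == "louvain":
        clustering = g.community_multilevel(weights="weight")
    else:
        clustering = g.community_infomap(edge_weights="weight")
    assignment = {g.vs[v]["name"]: int(m) for m, comm in enumerate(clustering) for v in comm}
    # isolated vertices may be absent from some clusterings; give them singleton modules
    nxt = max(assignment.values(), default=-1) + 1
    for name in network.genes:
        if name not in assignment:
            assignment[name] = nxt
            nxt += 1
    return Partition(method, assignment)


def fisher_enrichment(module_genes: set[str], background: set[str], term_genes: set[str]) -> float:
    """One-sided (over-representation) hypergeometric tail p for the 2x2
    module x term table, term genes restricted to the background."""
    if not module_genes or not background:
        raise ValueError("module and background must be non-empty")
    if not module_genes <= background:
        raise ValueError("module must be a subset of the background")
    M = len(background)
    n = len(term_genes & background)
    N = len(module_genes)
    k = len(module_genes & term_genes)
    return float(hypergeom.sf(k - 1, M, n, N))


@dataclass
class ModuleScore:
    module: int
    raw: float
    normalized: float = np.nan
    gene_scores: dict = field(default_factory=dict)
    significant_terms: tuple = ()


def cluster_bioscore(
    partition: Partition,
    catalog: AnnotationCatalog,
    source: str,
    t: float = 0.05,
    background: set[str] | None = None,
) -> tuple[dict[int, ModuleScore], float]:
    """Per-module and average Bioscore for one annotation source.

    The enrichment background defaults to the partition's own gene set.
    Returns (per-module scores, average normalized score).
    """
    terms = catalog.cancer_terms(source)
    if not terms:
        raise ValueError(f"catalog has no cancer-related {source} terms")
    if background is None:
        background = set(partition.assignment)
    scores: dict[int, ModuleScore] = {}
    for mod, genes in sorted(partition.modules().items()):
        pvals = np.array([fisher_enrichment(genes, background, catalog.terms[t_] & background)
                          for t_ in terms])
        adj = benjamini_hochberg(pvals)
        sig = {terms[i] for i in range(len(terms)) if adj[i] < t}
        gene_scores = {g: sum(1 for term in sig if g in catalog.terms[term]) for g in genes}
        scores[mod] = ModuleScore(
            module=mod,
            raw=float(sum(gene_scores.values())),
            gene_scores=gene_scores,
            significant_terms=tuple(sorted(sig)),
        )
    raws = np.array([s.raw for s in scores.values()])
    lo, hi = raws.min(), raws.max()
    for s in scores.values():
        s.normalized = 0.0 if hi == lo else (s.raw - lo) / (hi - lo)
    average = float(np.mean([s.normalized for s in scores.values()]))
    return scores, average


def bhi(partition: Partition, annotation: dict[str, set[str]]) -> float:
    """Biological homogeneity index of a partition.

    ``annotation`` maps gene -> set of functional classes.  Modules with
    fewer than two annotated genes do not qualify.
    """
    fractions = []
    for genes in partition.modules().values():
        annotated = [g for g in genes if annotation.get(g)]
        if len(annotated) < 2:
            continue
        hits = total = 0
        for a in annotated:
            for b in annotated:
                if a == b:
                    continue
                total += 1
                if annotation[a] & annotation[b]:
                    hits += 1
        fractions.append(hits / total)
    if not fractions:
        raise ValueError("no module with at least two annotated genes")
    return float(np.mean(fractions))


def evaluate_partitions(
    partitions: list[Partition],
    catalog: AnnotationCatalog,
    annotation: dict[str, set[str]] | None = None,
    t: float = 0.05,
) -> pd.DataFrame:
    """Score every partition (average Bioscore GO-BP / KEGG, average BHI,
    module count) and mark the best method.

    Best = highest average GO-BP Bioscore; ties break by average BHI, then
    method name.  ``annotation`` defaults to the catalog's full gene ->
    classes map.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    if annotation is None:
        annotation = catalog.gene_classes()
    rows = []
    for part in partitions:
        _, avg_gobp = cluster_bioscore(part, catalog, "GO-BP", t)
        _, avg_kegg = cluster_bioscore(part, catalog, "KEGG", t)
        try:
            avg_bhi = bhi(part, annotation)
        except ValueError:
            avg_bhi = float("nan")
        rows.append(
            {
                "method": part.method,
                "average_bioscore_gobp": avg_gobp,
                "average_bioscore_kegg": avg_kegg,
                "average_bhi": avg_bhi,
                "n_modules": part.n_modules,
            }
        )
    report = pd.DataFrame(rows).set_index("method")

    def rank_key(method: str):
        row = report.loc[method]
        b = row["average_bhi"]
        b = b if b == b else float("-inf")  # NaN BHI ranks worst
        return (-row["average_bioscore_gobp"], -b, method)

    best = min(report.index, key=rank_key)
    report["best"] = report.index == best
    return report
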