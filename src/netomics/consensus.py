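"""Cross-cancer, cross-split consensus biomarker extraction.

Module ids from independently clustered networks are not comparable, so
"same module in every dataset" is formalized through pairwise
co-membership: for each dataset's partition, take all unordered gene pairs
co-assigned to a module (restricted to the shared gene universe), intersect
the pair sets across all datasets (four cancer types x two splits), and
report the connected components (size >= 2) of the surviving pair graph as
consensus groups.  Genes left without a surviving partner are reported
separately as singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .communities import Partition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusGroup:
    genes: frozenset
    direction: str  # {"hypo", "hyper"}

    def __post_init__(self):
        if len(self.genes) < 2:
            raise ValueError("consensus groups hold at least two genes")


def co_membership_pairs(partition: Partition, universe: set[str]) -> set[frozenset]:
    """All unordered pairs of universe genes sharing a module id.

    Universe genes absent from the partition are dropped with a log entry.
    """
    if not universe:
        raise ValueError("empty gene universe")
    absent = universe - set(partition.assignment)
    if absent:
        logger.info("%d universe genes absent from partition; dropped", len(absent))
    pairs: set[frozenset] = set()
    for genes in partition.modules().values():
        members = sorted(genes & universe)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                pairs.add(frozenset((a, b)))
    return pairs


def consensus_groups(
    pairs_by_dataset: list[set[frozenset]], direction: str
) -> tuple[list[ConsensusGroup], set[str]]:
    """Intersect co-membership pair sets across datasets and return the
    connected components (size >= 2) plus surviving singleton genes.

    An empty intersection yields an empty result, not an error.
    """
    if not pairs_by_dataset:
        raise ValueError("no datasets given")
    common = set.intersection(*pairs_by_dataset)
    graph = nx.Graph()
    for pair in common:
        a, b = sorted(pair)
        graph.add_edge(a, b)
    groups = [
        ConsensusGroup(frozenset(comp), direction)
        for comp in nx.connected_components(graph)
        if len(comp) >= 2
    ]
    groups.sort(key=lambda g: sorted(g.genes)[0])
    paired = set().union(*(g.genes for g in groups)) if groups else set()
    all_universe = set()
    for pairs in pairs_by_dataset:
        for pair in pairs:
            all_universe |= set(pair)
    singletons = all_universe - paired
    return groups, singletons


def mutation_profile(
    mutations: pd.DataFrame,
    biomarkers: set[str],
    clinical: pd.DataFrame,
    keep_untreated_early: bool = True,
) -> pd.DataFrame:
    """Somatic mutation profile of the biomarker genes.

    Records are filtered to untreated stage-I/II patients (the cohort the
    survival analysis uses); per gene, distinct mutated patients are counted
    and normalized by the total number of patients with at least one
    mutation in the filtered table.  Variant classifications are tallied.
    """
    eligible = clinical.index
    if keep_untreated_early and {"treated", "stage"} <= set(clinical.columns):
        mask = (~clinical["treated"].astype(bool)) & clinical["stage"].isin(["I", "II"])
        eligible = clinical.index[mask]
    filt = mutations[mutations["Tumor_Sample_Barcode"].isin(set(eligible))]
    total_mutated = filt["Tumor_Sample_Barcode"].nunique()
    rows = []
    for gene in sorted(biomarkers):
        sub = filt[filt["Hugo_Symbol"] == gene]
        n_pat = sub["Tumor_Sample_Barcode"].nunique()
        tally = sub.drop_duplicates(["Tumor_Sample_Barcode", "Variant_Classification"])[
            "Variant_Classification"
        ].value_counts().to_dict()
        rows.append(
            {
                "gene": gene,
                "n_patients_mutated": n_pat,
                "normalized_fraction": n_pat / total_mutated if total_mutated else 0.0,
                "variant_tally": tally,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
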