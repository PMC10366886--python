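"""Differential expression / methylation calling and probe-gene pairing.

The calling thresholds follow the usual tumor-vs-normal conventions:

* a gene is differentially expressed (DE) when |log2FC| > 1.0 (strict) and
  Benjamini-Hochberg FDR < 0.05,
* a distal probe (>= 2 kb from every TSS, inclusive) is differentially
  methylated (DM) when |mean(tumor) - mean(normal)| >= 0.3 (inclusive) and
  its one-sided BH-adjusted p < 0.01,
* a DM probe is paired with its closest 10 upstream and 10 downstream DE
  genes and a pair is significant when a rank-sum test comparing the gene's
  expression between the 20% least- and most-methylated samples survives BH,
  subject to a beta-spread eligibility filter (>= 5% of betas below 0.3 and
  >= 5% above 0.3).

The DE engine here is a Welch t-test on log2(CPM+1) with a 0.5-CPM
pseudocount fold change; it is deliberately simple, exactly specified, and
pluggable -- the package's contribution is the downstream network pipeline,
not the differential-expression engine.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import GenomeAnnotation, ProbeManifest

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million, per sample."""
    libsize = counts.sum(axis=0)
    return counts / libsize * 1e6


def differential_expression(
    counts: pd.DataFrame,
    group: pd.Series,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Welch-t differential expression on log2(CPM+1).

    Returns a per-gene frame with columns ``log2fc``, ``p``, ``fdr``,
    ``tested`` and ``passes``; all-zero genes are flagged untested and never
    pass.  ``passes`` is |log2fc| > lfc_threshold (strict) and fdr <
    fdr_threshold.
    """
    tum = [s for s in counts.columns if group[s] == "tumor"]
    nor = [s for s in counts.columns if group[s] == "normal"]
    if len(tum) < 2 or len(nor) < 2:
        raise ValueError("need at least two samples per group")

    c = cpm(counts)
    mean_t = c[tum].mean(axis=1)
    mean_n = c[nor].mean(axis=1)
    log2fc = np.log2((mean_t + 0.5) / (mean_n + 0.5))

    logc = np.log2(c + 1.0)
    tested = counts.sum(axis=1) > 0
    res = stats.ttest_ind(
        logc[tum].values, logc[nor].values, axis=1, equal_var=False
    )
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance-in-both-groups genes give NaN: no evidence against the null
    p = np.where(np.isnan(p), 1.0, p)

    out = pd.DataFrame(
        {"log2fc": log2fc, "p": np.where(tested, p, np.nan), "tested": tested},
        index=counts.index,
    )
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = benjamini_hochberg(out.loc[tested, "p"].values)
    out["passes"] = tested & (out["log2fc"].abs() > lfc_threshold) & (out["fdr"] < fdr_threshold)
    n_skip = int((~tested).sum())
    if n_skip:
        logger.info("%d all-zero genes flagged untested", n_skip)
    return out


# ---------------------------------------------------------------------------
# distal probes & differential methylation
# ---------------------------------------------------------------------------

def select_distal_probes(
    manifest: ProbeManifest, annotation: GenomeAnnotation, min_dist: int = 2000
) -> set[str]:
    """Probes whose minimum |distance| to any TSS is >= ``min_dist`` (inclusive).

    Probes on chromosomes with no annotated gene are retained (infinite
    distance).
    """
    ann = annotation.table
    if len(ann) == 0:
        raise ValueError("annotation is empty")
    man = manifest.table
    kept: set[str] = set()
    tss_by_chrom = {c: np.sort(sub["tss"].values) for c, sub in ann.groupby("chromosome")}
    for chrom, sub in man.groupby("chromosome"):
        tss = tss_by_chrom.get(chrom)
        if tss is None:
            kept.update(sub["probe_id"])
            continue
        pos = sub["position"].values
        idx = np.searchsorted(tss, pos)
        left = np.where(idx > 0, np.abs(pos - tss[np.maximum(idx - 1, 0)]), np.inf)
        right = np.where(idx < len(tss), np.abs(tss[np.minimum(idx, len(tss) - 1)] - pos), np.inf)
        mind = np.minimum(left, right)
        kept.update(sub.loc[mind >= min_dist, "probe_id"])
    return kept


def differential_methylation(
    betas: pd.DataFrame,
    group: pd.Series,
    sig_dif: float = 0.3,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """One-sided Welch t-tests per probe, one per direction.

    A probe is a hypo candidate when mean(tumor) < mean(normal) (tested with
    alternative tumor < normal) and a hyper candidate in the opposite case;
    BH is applied within each direction.  ``passes`` requires |delta_beta|
    >= sig_dif (inclusive) and adjusted p < alpha (strict).  Probes constant
    across all samples are skipped with a log entry.
    """
    tum = [s for s in betas.columns if group[s] == "tumor"]
    nor = [s for s in betas.columns if group[s] == "normal"]
    if len(tum) < 2 or len(nor) < 2:
        raise ValueError("need at least two samples per group")
    if ((betas.values < 0) | (betas.values > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")

    x = betas[tum].values
    y = betas[nor].values
    delta = x.mean(axis=1) - y.mean(axis=1)
    constant = betas.nunique(axis=1).values == 1
    if constant.any():
        logger.info("%d constant probes skipped (p undefined)", int(constant.sum()))

    p_less = np.asarray(
        stats.ttest_ind(x, y, axis=1, equal_var=False, alternative="less").pvalue, dtype=float
    )
    p_greater = np.asarray(
        stats.ttest_ind(x, y, axis=1, equal_var=False, alternative="greater").pvalue, dtype=float
    )

    out = pd.DataFrame(index=betas.index)
    out["delta_beta"] = delta
    out["direction"] = np.where(delta < 0, "hypo", np.where(delta > 0, "hyper", "none"))
    out.loc[constant, "direction"] = "none"
    out["p"] = np.where(out["direction"] == "hypo", p_less,
                        np.where(out["direction"] == "hyper", p_greater, np.nan))
    out["adj_p"] = np.nan
    for direction in ("hypo", "hyper"):
        mask = (out["direction"] == direction) & ~constant & ~out["p"].isna()
        if mask.any():
            out.loc[mask, "adj_p"] = benjamini_hochberg(out.loc[mask, "p"].values)
    out["passes"] = (
        (out["direction"] != "none")
        & (out["delta_beta"].abs() >= sig_dif)
        & (out["adj_p"] < alpha)
    )
    return out


# ---------------------------------------------------------------------------
# probe-gene pairing
# ---------------------------------------------------------------------------

def nearest_genes(
    probe: str,
    de_genes: set[str],
    annotation: GenomeAnnotation,
    manifest: ProbeManifest,
    n_up: int = 10,
    n_down: int = 10,
) -> list[str]:
    """The ``n_up`` nearest passing DE genes with TSS below the probe position
    and ``n_down`` nearest with TSS above it, on the probe's chromosome.

    Distances are genomic-coordinate distances to the TSS, ignoring gene
    strand.  Equal-distance ties for the last slot break by gene_id order.
    """
    man = manifest.table
    row = man[man["probe_id"] == probe]
    if len(row) == 0:
        raise KeyError(f"probe '{probe}' not in manifest")
    chrom = row["chromosome"].iloc[0]
    pos = int(row["position"].iloc[0])
    ann = annotation.table
    cand = ann[(ann["chromosome"] == chrom) & ann["gene_id"].isin(de_genes)]
    if len(cand) == 0:
        return []
    dist = (cand["tss"] - pos).abs()
    ordered = cand.assign(_d=dist).sort_values(["_d", "gene_id"])
    up = ordered[ordered["tss"] < pos].head(n_up)
    down = ordered[ordered["tss"] > pos].head(n_down)
    return list(up["gene_id"]) + list(down["gene_id"])


def pair_significance(
    beta_row,
    expr_row,
    q: float = 0.2,
    min_group: int = 5,
    spread_fraction: float = 0.05,
    spread_cutoff: float = 0.3,
) -> float:
    """Rank-sum p for expression between the lowest-q and highest-q beta samples.

    A pair is eligible only when at least ``spread_fraction`` of the beta
    values fall below ``spread_cutoff`` and the same fraction falls above it;
    ineligible pairs return NaN.  Raises when the extreme groups would hold
    fewer than ``min_group`` samples.
    """
    b = np.asarray(beta_row, dtype=float)
    e = np.asarray(expr_row, dtype=float)
    n = b.size
    k = int(np.floor(q * n))
    if k < min_group:
        raise ValueError(f"extreme groups of {k} samples; need >= {min_group}")
    frac_low = np.mean(b < spread_cutoff)
    frac_high = np.mean(b > spread_cutoff)
    if frac_low < spread_fraction or frac_high < spread_fraction:
        logger.debug("pair ineligible: beta spread %.3f/%.3f", frac_low, frac_high)
        return float("nan")
    order = np.argsort(b, kind="stable")
    lo, hi = e[order[:k]], e[order[-k:]]
    # exact null for small extreme groups (cheap and matches the rank-sum
    # minimum under complete separation); normal approximation otherwise
    method = "exact" if k <= 12 and len(np.unique(np.concatenate([lo, hi]))) == 2 * k else "auto"
    return float(stats.mannwhitneyu(lo, hi, alternative="two-sided", method=method).pvalue)


def pair_probes_with_genes(
    dm: pd.DataFrame,
    de: pd.DataFrame,
    betas: pd.DataFrame,
    log_expr: pd.DataFrame,
    annotation: GenomeAnnotation,
    manifest: ProbeManifest,
    n_up: int = 10,
    n_down: int = 10,
    pair_alpha: float = 0.05,
) -> pd.DataFrame:
    """Candidate probe-gene pairs for all passing DM probes, with rank-sum
    p-values BH-adjusted over all eligible pairs.

    Returns columns ``probe_id``, ``gene_id``, ``pair_p``, ``pair_adj_p``,
    ``significant``.
    """
    de_set = set(de.index[de["passes"]])
    rows = []
    for probe in dm.index[dm["passes"]]:
        for gene in nearest_genes(probe, de_set, annotation, manifest, n_up, n_down):
            p = pair_significance(betas.loc[probe].values, log_expr.loc[gene].values)
            rows.append({"probe_id": probe, "gene_id": gene, "pair_p": p})
    pairs = pd.DataFrame(rows, columns=["probe_id", "gene_id", "pair_p"])
    pairs["pair_adj_p"] = np.nan
    ok = ~pairs["pair_p"].isna()
    if ok.any():
        pairs.loc[ok, "pair_adj_p"] = benjamini_hochberg(pairs.loc[ok, "pair_p"].values)
    pairs["significant"] = pairs["pair_adj_p"] < pair_alpha
    return pairs


# ---------------------------------------------------------------------------
# gene-level methylation & DEMG
# ---------------------------------------------------------------------------

def gene_level_methylation(pairs: pd.DataFrame, betas: pd.DataFrame) -> pd.DataFrame:
    """Per gene and sample, the arithmetic mean beta over its significant
    paired probes.  Genes with zero significant pairs are excluded."""
    sig = pairs[pairs["significant"]] if "significant" in pairs.columns else pairs
    missing = set(sig["probe_id"]) - set(betas.index)
    if missing:
        raise KeyError(f"paired probes missing from beta matrix: {sorted(missing)[:5]}")
    rows = {}
    for gene, sub in sig.groupby("gene_id"):
        rows[gene] = betas.loc[sub["probe_id"].unique()].mean(axis=0)
    if not rows:
        return pd.DataFrame(columns=betas.columns)
    return pd.DataFrame(rows).T


def gene_methylation_direction(pairs: pd.DataFrame, dm: pd.DataFrame) -> dict[str, str]:
    """Majority-vote hypo/hyper direction per gene over its significant
    paired probes; ties are left unassigned (logged)."""
    sig = pairs[pairs["significant"]] if "significant" in pairs.columns else pairs
    out: dict[str, str] = {}
    for gene, sub in sig.groupby("gene_id"):
        dirs = dm.loc[sub["probe_id"].unique(), "direction"]
        n_hypo = int((dirs == "hypo").sum())
        n_hyper = int((dirs == "hyper").sum())
        if n_hypo > n_hyper:
            out[gene] = "hypo"
        elif n_hyper > n_hypo:
            out[gene] = "hyper"
        else:
            logger.info("gene %s has tied hypo/hyper probe votes; unassigned", gene)
    return out


def demg(
    de: pd.DataFrame,
    glm: pd.DataFrame,
    dm_direction_by_gene: dict[str, str],
) -> tuple[set[str], set[str]]:
    """DEMG sets: passing DE genes intersected with genes whose paired
    probes are (majority) hypo-, respectively hyper-methylated."""
    de_set = set(de.index[de["passes"]])
    meth_genes = set(glm.index)
    hypo = {g for g, d in dm_direction_by_gene.items() if d == "hypo"} & de_set & meth_genes
    hyper = {g for g, d in dm_direction_by_gene.items() if d == "hyper"} & de_set & meth_genes
    return hypo, hyper
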