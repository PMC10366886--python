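"""Weighted multi-omics prognostic score and survival analysis.

Per patient and gene the prognostic score combines three omics layers,

    score = w_e * expr + w_m * beta + w_mut * mut,

with expr the per-gene min-max of log2(raw count + 1) in [0, 1], beta the
gene-level methylation in [0, 1], mut the binary mutation status, and
default weights (0.5, 0.3, 0.2) summing to 1 -- so the score itself lies in
[0, 1].  Per gene, high/low levels are mean +/- one sample standard
deviation of its scores; per cancer type, the cutoffs actually used for
labeling are the averages of those per-gene levels over the DEMG_Common
genes.  Scores strictly below the average low cutoff are "low", strictly
above the average high cutoff "high", and everything else (boundaries
included) "normal".

Cox proportional-hazards fits (lifelines, Breslow ties) use "normal" as
the reference level; Kaplan-Meier curves use the product-limit estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrognosticWeights:
    w_expr: float = 0.5
    w_meth: float = 0.3
    w_mut: float = 0.2

    def __post_init__(self):
        w = (self.w_expr, self.w_meth, self.w_mut)
        if any(x < 0 for x in w):
            raise ValueError("weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


ALT_WEIGHTS = PrognosticWeights(0.4, 0.4, 0.2)


# ---------------------------------------------------------------------------
# score components
# ---------------------------------------------------------------------------

def normalize_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(count + 1) followed by per-gene min-max across patients.

    Constant genes map to all zeros (flagged).
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    logc = np.log2(counts.astype(float) + 1.0)
    lo = logc.min(axis=1)
    hi = logc.max(axis=1)
    span = hi - lo
    const = span == 0
    if const.any():
        logger.info("%d constant genes map to 0 under min-max", int(const.sum()))
    span = span.replace(0, 1.0)
    return logc.sub(lo, axis=0).div(span, axis=0)


def mutation_matrix(mutations: pd.DataFrame, genes: list[str], patients: list[str]) -> pd.DataFrame:
    """Binary genes x patients mutation-status matrix (1 iff >= 1 record)."""
    mat = pd.DataFrame(0, index=genes, columns=patients, dtype=int)
    hits = mutations[
        mutations["Hugo_Symbol"].isin(genes) & mutations["Tumor_Sample_Barcode"].isin(patients)
    ]
    for g, s in zip(hits["Hugo_Symbol"], hits["Tumor_Sample_Barcode"]):
        mat.loc[g, s] = 1
    return mat


def mutation_indicator(mutations: pd.DataFrame, gene: str, patient: str) -> int:
    """1 iff the patient carries at least one somatic record for the gene."""
    hit = (mutations["Hugo_Symbol"] == gene) & (mutations["Tumor_Sample_Barcode"] == patient)
    return int(hit.any())


def prognostic_score(expr_norm, beta, mut, weights: PrognosticWeights = PrognosticWeights()):
    """The weighted multi-omics score; components must be in range."""
    e = np.asarray(expr_norm, dtype=float)
    b = np.asarray(beta, dtype=float)
    m = np.asarray(mut, dtype=float)
    for name, v, lo, hi in (("expression", e, 0, 1), ("methylation", b, 0, 1), ("mutation", m, 0, 1)):
        if np.any((v < lo) | (v > hi)):
            raise ValueError(f"{name} component out of [0, 1]")
    return weights.w_expr * e + weights.w_meth * b + weights.w_mut * m


def score_matrix(
    counts: pd.DataFrame,
    gene_betas: pd.DataFrame,
    mutations: pd.DataFrame,
    genes: list[str],
    weights: PrognosticWeights = PrognosticWeights(),
) -> pd.DataFrame:
    """Patients x genes prognostic-score matrix over the DEMG_Common genes.

    Genes without gene-level methylation contribute beta 0 (flagged): the
    score stays defined and the missingness is auditable via the log.
    """
    patients = list(counts.columns)
    expr = normalize_expression(counts.loc[genes])
    missing_beta = [g for g in genes if g not in gene_betas.index]
    if missing_beta:
        logger.info("%d genes without gene-level methylation; beta imputed 0", len(missing_beta))
    betas = pd.DataFrame(0.0, index=genes, columns=patients)
    present = [g for g in genes if g in gene_betas.index]
    if present:
        betas.loc[present] = gene_betas.loc[present, patients].values
    mut = mutation_matrix(mutations, genes, patients)
    scores = prognostic_score(expr.values, betas.values, mut.values, weights)
    return pd.DataFrame(scores, index=genes, columns=patients).T


# ---------------------------------------------------------------------------
# cutoffs and labels
# ---------------------------------------------------------------------------

def gene_level_cutoffs(scores) -> tuple[float, float]:
    """(mean + SD, mean - SD) of one gene's scores (sample SD, ddof=1)."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least two patients")
    m, sd = s.mean(), s.std(ddof=1)
    return float(m + sd), float(m - sd)


def cancer_cutoffs(per_gene_cutoffs: list[tuple[float, float]]) -> tuple[float, float]:
    """Average the per-gene high/low levels over the DEMG_Common genes."""
    if not per_gene_cutoffs:
        raise ValueError("empty cutoff list")
    highs, lows = zip(*per_gene_cutoffs)
    return float(np.mean(highs)), float(np.mean(lows))


def label_scores(score, avg_high: float, avg_low: float):
    """low / normal / high labels; boundary scores are 'normal'."""
    if avg_low > avg_high:
        raise ValueError("avg_low must not exceed avg_high")
    s = np.asarray(score, dtype=float)
    lab = np.where(s < avg_low, "low", np.where(s > avg_high, "high", "normal"))
    return lab if s.shape else str(lab)


# ---------------------------------------------------------------------------
# survival records and models
# ---------------------------------------------------------------------------

def survival_records(clinical: pd.DataFrame) -> pd.DataFrame:
    """(time, event) per patient: days_to_death when dead (event 1), else
    days_to_last_followup (event 0).  Patients with missing or non-positive
    time are dropped with a log entry."""
    rows = {}
    dropped = 0
    for sample, row in clinical.iterrows():
        dead = str(row["vital_status"]).lower() == "dead"
        t = row["days_to_death"] if dead else row["days_to_last_followup"]
        if pd.isna(t) or t <= 0:
            dropped += 1
            continue
        rows[sample] = {"time": float(t), "event": int(dead)}
    if dropped:
        logger.info("%d patients dropped (missing/non-positive survival time)", dropped)
    return pd.DataFrame.from_dict(rows, orient="index")


def kaplan_meier(records: pd.DataFrame, groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group label.

    Returns per label a frame indexed by time with a ``survival`` column.
    """
    out = {}
    for label in pd.unique(groups):
        members = groups.index[groups == label]
        sub = records.loc[records.index.intersection(members)]
        if len(sub) == 0:
            raise ValueError(f"group '{label}' is empty")
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"])
        curve = km.survival_function_
        curve.columns = ["survival"]
        out[str(label)] = curve
    return out


def cox_ph(labels: pd.Series, records: pd.DataFrame, reference: str = "normal") -> pd.DataFrame:
    """Cox PH with the label as a categorical covariate, ``reference`` as
    the baseline level; Breslow tie handling (lifelines default).

    Returns one row per non-reference level present: hazard_ratio, p
    (Wald), n and deaths at that level.
    """
    common = records.index.intersection(labels.index)
    df = records.loc[common].copy()
    df["label"] = labels.loc[common].astype(str)
    present = [l for l in df["label"].unique()]
    if len(present) < 2:
        raise ValueError("need at least two label levels present")
    if df["event"].sum() == 0:
        raise ValueError("no events observed")
    others = sorted(l for l in present if l != reference)
    design = df[["time", "event"]].copy()
    for lvl in others:
        design[f"level_{lvl}"] = (df["label"] == lvl).astype(float)
    cph = CoxPHFitter()
    cph.fit(design, duration_col="time", event_col="event")
    rows = []
    for lvl in others:
        cov = f"level_{lvl}"
        rows.append(
            {
                "level": lvl,
                "hazard_ratio": float(np.exp(cph.params_[cov])),
                "p": float(cph.summary.loc[cov, "p"]),
                "n_at_level": int((df["label"] == lvl).sum()),
                "deaths_at_level": int(df.loc[df["label"] == lvl, "event"].sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def survival_screen(
    scores: pd.DataFrame,
    records: pd.DataFrame,
    hr_min: float = 1.0,
    p_max: float = 0.05,
    cutoffs: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Label patients per gene with the cancer-level cutoffs, fit Cox PH per
    gene, and keep (gene, level) rows with HR > hr_min and p < p_max.

    ``scores`` is patients x genes.  ``cutoffs`` is (avg_high, avg_low); by
    default it is derived from the score matrix itself by averaging the
    per-gene mean +/- SD levels.
    """
    if cutoffs is None:
        per_gene = [gene_level_cutoffs(scores[g].values) for g in scores.columns]
        avg_high, avg_low = cancer_cutoffs(per_gene)
    else:
        avg_high, avg_low = cutoffs
    rows = []
    for gene in scores.columns:
        labels = pd.Series(label_scores(scores[gene].values, avg_high, avg_low),
                           index=scores.index)
        try:
            res = cox_ph(labels, records)
        except (ValueError, ConvergenceError) as exc:  # degenerate labelings are skipped
            logger.debug("gene %s skipped in screen: %s", gene, exc)
            continue
        for _, r in res.iterrows():
            if r["hazard_ratio"] > hr_min and r["p"] < p_max:
                rows.append({"gene": gene, **r.to_dict()})
    cols = ["gene", "level", "hazard_ratio", "p", "n_at_level", "deaths_at_level"]
    return pd.DataFrame(rows, columns=cols)


def single_omics_screen(
    data_type: str,
    counts: pd.DataFrame | None = None,
    gene_betas: pd.DataFrame | None = None,
    mutations: pd.DataFrame | None = None,
    genes: list[str] | None = None,
    records: pd.DataFrame | None = None,
    hr_min: float = 1.0,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Survival screen from a single omics layer.

    Expression and methylation reuse the cutoff/labeling pipeline on the
    single normalized component; mutation uses the binary status directly
    as the group label.
    """
    if records is None or genes is None:
        raise ValueError("records and genes are required")
    if data_type == "expression":
        comp = normalize_expression(counts.loc[genes]).T
        return survival_screen(comp, records, hr_min, p_max)
    if data_type == "methylation":
        present = [g for g in genes if g in gene_betas.index]
        comp = gene_betas.loc[present].T
        return survival_screen(comp, records, hr_min, p_max)
    if data_type == "mutation":
        patients = [p for p in records.index]
        mat = mutation_matrix(mutations, genes, patients)
        rows = []
        for gene in genes:
            labels = pd.Series(np.where(mat.loc[gene] == 1, "mutated", "normal"),
                               index=patients)
            try:
                res = cox_ph(labels, records)
            except (ValueError, ConvergenceError):
                continue
            for _, r in res.iterrows():
                if r["hazard_ratio"] > hr_min and r["p"] < p_max:
                    rows.append({"gene": gene, **r.to_dict()})
        cols = ["gene", "level", "hazard_ratio", "p", "n_at_level", "deaths_at_level"]
        return pd.DataFrame(rows, columns=cols)
    raise ValueError(f"unknown data type '{data_type}'")


def compare_weight_schemes(
    weights_a: PrognosticWeights,
    weights_b: PrognosticWeights,
    counts: pd.DataFrame,
    gene_betas: pd.DataFrame,
    mutations: pd.DataFrame,
    genes: list[str],
    records: pd.DataFrame,
    hr_min: float = 1.0,
    p_max: float = 0.05,
) -> dict:
    """Run the survival screen under two weight triples and compare the
    significant-gene sets."""
    out = {}
    for tag, w in (("a", weights_a), ("b", weights_b)):
        sm = score_matrix(counts, gene_betas, mutations, genes, w)
        out[tag] = survival_screen(sm, records, hr_min, p_max)
    genes_a = set(out["a"]["gene"])
    genes_b = set(out["b"]["gene"])
    return {
        "screen_a": out["a"],
        "screen_b": out["b"],
        "n_significant_a": len(genes_a),
        "n_significant_b": len(genes_b),
        "only_a": sorted(genes_a - genes_b),
        "only_b": sorted(genes_b - genes_a),
    }
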