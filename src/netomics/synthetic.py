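"""Seeded synthetic multi-omics cohort generator with planted ground truth.

The generator emulates the data layers of a TCGA-style tumor/normal cohort:

* gene-level RNA-seq raw counts (negative binomial, lognormal baselines,
  planted differential expression),
* probe-level methylation beta values (beta/logit-normal, planted hypo-/
  hyper-methylation shifts),
* somatic mutation records (Bernoulli, elevated rate on planted genes),
* a clinical table with vital status, follow-up times, stage and a
  treatment flag, where survival times are exponential with a hazard tied
  to the planted prognostic genes.

Planted gene modules share a latent Gaussian factor (added on the log-mean
scale for counts and on the logit scale for betas) inducing the positive
gene-gene correlation the downstream network stages consume.  Module
membership is identical across the four simulated cancer types, which is
the structure the cross-cancer consensus step is designed to recover.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)

CANCER_TYPES = ("BRCA", "COAD", "KIRC", "LUSC")

VARIANT_CLASSES = ("Missense_Mutation", "Nonsense_Mutation", "Silent", "Frame_Shift_Del")
_VARIANT_PROBS = (0.6, 0.1, 0.2, 0.1)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeAnnotation:
    """Gene id, chromosome, TSS position and strand for every gene."""

    table: pd.DataFrame  # columns: gene_id, chromosome, tss, strand

    def __post_init__(self):
        t = self.table
        if t["gene_id"].duplicated().any():
            raise ValueError("gene_ids must be unique")
        if (t["tss"] < 0).any():
            raise ValueError("tss positions must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])


@dataclass(frozen=True)
class ProbeManifest:
    """Probe id, chromosome and base-pair position for every probe.

    A ``home_gene`` bookkeeping column records which gene's neighbourhood a
    probe was placed in; downstream operations never rely on it.
    """

    table: pd.DataFrame  # columns: probe_id, chromosome, position[, home_gene]

    def __post_init__(self):
        if self.table["probe_id"].duplicated().any():
            raise ValueError("probe_ids must be unique")
        if (self.table["position"] < 0).any():
            raise ValueError("probe positions must be non-negative")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])


@dataclass(frozen=True)
class ModuleSpec:
    """One planted cross-cancer gene module."""

    name: str
    genes: tuple[str, ...]
    direction: str = "hypo"  # methylation direction of the module's probes

    def __post_init__(self):
        if self.direction not in ("hypo", "hyper"):
            raise ValueError("direction must be 'hypo' or 'hyper'")


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of one simulated cancer-type cohort.

    Defaults are the study conditions every test and the acceptance run use:
    ~200 tumor / 50 normal samples, 1000 genes, 2000 probes, planted
    |log2FC| = 2 (> the 1.0 calling threshold), planted |delta beta| = 0.4
    (> the 0.3 calling threshold), and a per-SD log-hazard of 1.5 for the
    planted prognostic burden (hazard ratio ~4.5 per burden SD, the strength
    of a strong composite prognostic signature).
    """

    n_tumor: int = 200
    n_normal: int = 50
    n_genes: int = 1000
    n_probes: int = 2000
    nb_dispersion: float = 0.3
    planted_log2fc: float = 2.0
    planted_delta_beta: float = 0.4
    module_spec: tuple[ModuleSpec, ...] = ()
    de_only_genes: tuple[str, ...] = ()
    demg_background: tuple[ModuleSpec, ...] = ()  # DE+DM but no shared factor
    prognostic_genes: dict = field(default_factory=dict)  # gene -> +1/-1
    mutated_genes: tuple[str, ...] = ()
    hazard_beta: float = 1.5
    censor_rate: float = 0.4
    median_survival_days: float = 900.0
    mutation_rate_planted: float = 0.3
    background_mutations_per_patient: float = 5.0
    untreated_early_fraction: float = 0.8
    factor_loading_expr: float = 0.6
    factor_loading_meth: float = 1.0
    probes_per_demg: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.planted_log2fc <= 1.0:
            raise ValueError("planted_log2fc must exceed 1.0")
        if self.planted_delta_beta < 0.3:
            raise ValueError("planted_delta_beta must be >= 0.3")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need at least two samples per group")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class MultiOmicsCohort:
    """Aligned multi-omics tables for one cancer type (or one split of it)."""

    counts: pd.DataFrame     # genes x samples, non-negative integers
    betas: pd.DataFrame      # probes x samples, in [0, 1]
    mutations: pd.DataFrame  # columns: Tumor_Sample_Barcode, Hugo_Symbol, Variant_Classification
    clinical: pd.DataFrame   # indexed by sample
    group: pd.Series         # sample -> {"tumor", "normal"}
    cancer_type: str = "SYN"

    def __post_init__(self):
        samples = list(self.counts.columns)
        if list(self.betas.columns) != samples or list(self.clinical.index) != samples:
            raise ValueError("sample sets must be aligned across all tables")
        if ((self.betas.values < 0) | (self.betas.values > 1)).any():
            raise ValueError("beta values must lie in [0, 1]")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, samples: list[str]) -> "MultiOmicsCohort":
        samples = list(samples)
        mut = self.mutations[self.mutations["Tumor_Sample_Barcode"].isin(samples)]
        return MultiOmicsCohort(
            counts=self.counts[samples],
            betas=self.betas[samples],
            mutations=mut.reset_index(drop=True),
            clinical=self.clinical.loc[samples],
            group=self.group.loc[samples],
            cancer_type=self.cancer_type,
        )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of every planted effect, the oracle for recovery tests."""

    de_genes: tuple[str, ...]
    dm_probes_hypo: tuple[str, ...]
    dm_probes_hyper: tuple[str, ...]
    module_genes: dict          # module name -> tuple of genes
    module_direction: dict      # module name -> {"hypo", "hyper"}
    prognostic_genes: dict      # gene -> sign of survival effect (+1 poor prognosis)
    mutated_genes: tuple[str, ...]
    probe_gene: dict            # planted DM probe -> target gene


# ---------------------------------------------------------------------------
# annotation / manifest
# ---------------------------------------------------------------------------

def generate_annotation(
    n_genes: int,
    n_probes: int,
    seed: int = 0,
    distal_fraction: float = 0.7,
    n_chromosomes: int = 4,
    gene_spacing: int = 50_000,
) -> tuple[GenomeAnnotation, ProbeManifest]:
    """Place genes on linear chromosomes and probes around their TSSs.

    A ``distal_fraction`` share of probes is placed 5-15 kb downstream of a
    gene's TSS (hence >= 2 kb from every TSS given the 50 kb gene spacing);
    the remainder lands within +/-1.5 kb of a TSS (proximal).  Distal probes
    cycle through the genes so every gene owns at least one distal probe
    whenever ``distal_fraction * n_probes >= n_genes``.
    """
    if n_genes < 2 or n_probes < 1:
        raise ValueError("need n_genes >= 2 and n_probes >= 1")
    rng = np.random.default_rng(seed)

    per_chrom = int(math.ceil(n_genes / n_chromosomes))
    chrom = [f"chr{(i // per_chrom) + 1}" for i in range(n_genes)]
    idx_on_chrom = np.zeros(n_genes, dtype=int)
    counters = {}
    for i, c in enumerate(chrom):
        counters[c] = counters.get(c, 0) + 1
        idx_on_chrom[i] = counters[c]
    jitter = rng.integers(-5_000, 5_001, size=n_genes)
    tss = idx_on_chrom * gene_spacing + jitter
    strand = rng.choice(["+", "-"], size=n_genes)
    ann = pd.DataFrame(
        {
            "gene_id": [f"G{i:04d}" for i in range(n_genes)],
            "chromosome": chrom,
            "tss": tss.astype(int),
            "strand": strand,
        }
    )

    n_distal = int(math.ceil(distal_fraction * n_probes))
    rows = []
    for p in range(n_probes):
        if p < n_distal:
            g = p % n_genes
            offset = int(rng.integers(5_000, 15_001))
        else:
            g = int(rng.integers(0, n_genes))
            offset = int(rng.integers(-1_500, 1_500))
        rows.append(
            {
                "probe_id": f"cg{p:06d}",
                "chromosome": ann.loc[g, "chromosome"],
                "position": max(0, int(ann.loc[g, "tss"]) + offset),
                "home_gene": ann.loc[g, "gene_id"],
            }
        )
    manifest = pd.DataFrame(rows)
    return GenomeAnnotation(ann), ProbeManifest(manifest)


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default study conditions: planted modules, background DEMGs,
    DE-only genes, prognostic genes and mutated genes over the default
    1000-gene genome of :func:`generate_annotation` (250 genes per
    chromosome, contiguous blocks).

    Planted classes occupy direction-coherent genome blocks: each hypo
    module opens one of chr1-chr3, the hyper module opens chr4, background
    DEMG genes sit further along the same chromosomes, and DE-only genes at
    the chromosome ends.  Methylation probes pair with the nearest DE genes,
    so keeping each neighbourhood single-direction mirrors the regional
    coherence of real distal methylation domains.
    """
    gid = lambda i: f"G{i:04d}"
    rg = lambda a, b: tuple(gid(i) for i in range(a, b))
    modules = (
        ModuleSpec("M1", rg(0, 12), "hypo"),       # chr1 head
        ModuleSpec("M2", rg(250, 262), "hypo"),    # chr2 head
        ModuleSpec("M3", rg(500, 512), "hypo"),    # chr3 head
        ModuleSpec("M4", rg(750, 760), "hyper"),   # chr4 head
    )
    background = (
        ModuleSpec("bg_hypo", rg(30, 47) + rg(280, 297) + rg(530, 546), "hypo"),
        ModuleSpec("bg_hyper", rg(780, 805), "hyper"),
    )
    # DE-only genes carry no planted probes; the blocks placed right after
    # each module buffer the probe pairing windows so module probes do not
    # reach into the background blocks (and vice versa)
    de_only = (rg(12, 24) + rg(262, 274) + rg(512, 524) + rg(762, 774)
               + rg(200, 213) + rg(450, 463) + rg(700, 713) + rg(950, 963))
    cfg = CohortConfig(
        module_spec=modules,
        demg_background=background,
        de_only_genes=de_only,
        prognostic_genes={gid(i): +1 for i in range(0, 4)},
        mutated_genes=rg(0, 4) + rg(330, 338),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _censoring_horizon(rate_cfg: float, lam0: float) -> float:
    """Upper bound of the uniform censoring horizon such that the expected
    censored fraction at the baseline hazard equals ``rate_cfg``."""
    if rate_cfg <= 0:
        return float("inf")
    # P(censored) = (1 - exp(-x)) / x with x = lam0 * h, decreasing from 1 to 0
    f = lambda x: (1.0 - math.exp(-x)) / x - rate_cfg
    x = brentq(f, 1e-9, 1e6)
    return x / lam0


def generate_cohort(
    config: CohortConfig,
    annotation: GenomeAnnotation,
    manifest: ProbeManifest,
    cancer_type: str = "SYN",
) -> tuple[MultiOmicsCohort, PlantedTruth]:
    """Draw one tumor/normal multi-omics cohort with planted ground truth."""
    config.validate()
    ann = annotation.table
    man = manifest.table
    genes = list(ann["gene_id"])
    gene_index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(config.seed)

    n_t, n_n = config.n_tumor, config.n_normal
    n_s = n_t + n_n
    samples = [f"{cancer_type}-T{i:04d}" for i in range(n_t)] + [
        f"{cancer_type}-N{i:04d}" for i in range(n_n)
    ]
    is_tumor = np.array([True] * n_t + [False] * n_n)
    group = pd.Series(np.where(is_tumor, "tumor", "normal"), index=samples, name="group")

    planted_sets = list(config.module_spec) + list(config.demg_background)
    for spec in planted_sets:
        missing = set(spec.genes) - set(genes)
        if missing:
            raise ValueError(f"planted genes not in annotation: {sorted(missing)}")
    demg_genes = [g for spec in planted_sets for g in spec.genes]
    de_genes = demg_genes + [g for g in config.de_only_genes if g not in demg_genes]
    direction_of = {g: spec.direction for spec in planted_sets for g in spec.genes}

    # --- latent module factors (shared across omics layers) ----------------
    factors = {spec.name: rng.standard_normal(n_s) for spec in config.module_spec}
    gene_module = {g: spec.name for spec in config.module_spec for g in spec.genes}

    # --- expression counts --------------------------------------------------
    # hypo-direction planted genes are up-regulated (hypomethylation ->
    # activation), hyper-direction genes down-regulated (silencing); DE-only
    # genes alternate sign.  Planted baselines are damped so the planted
    # read mass keeps tumor library sizes comparable to normals.
    base_mean = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=len(genes))
    fc_sign = {}
    for k, g in enumerate(de_genes):
        if g in direction_of:
            fc_sign[g] = -1.0 if direction_of[g] == "hyper" else 1.0
        else:
            fc_sign[g] = 1.0 if k % 2 == 0 else -1.0
        # damp up-regulated baselines / lift down-regulated ones so planted
        # genes keep library sizes comparable and tumor counts informative
        base_mean[gene_index[g]] *= 0.5 if fc_sign[g] > 0 else 2.0
    log_mu = np.log(base_mean)[:, None] * np.ones((1, n_s))
    fc = np.log(2.0) * config.planted_log2fc
    for g, s in fc_sign.items():
        log_mu[gene_index[g], is_tumor] += s * fc
    for g, mname in gene_module.items():
        # methylation-expression coupling: the shared factor raises
        # expression in hypo modules and silences it in hyper modules
        s = -1.0 if direction_of[g] == "hyper" else 1.0
        log_mu[gene_index[g], :] += s * config.factor_loading_expr * factors[mname]
    mu = np.exp(log_mu)
    size = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    counts = pd.DataFrame(counts, index=genes, columns=samples)

    # --- methylation betas --------------------------------------------------
    # pick planted probes: distal probes whose neighbourhood gene is a DEMG gene
    probes = list(man["probe_id"])
    home = dict(zip(man["probe_id"], man.get("home_gene", pd.Series(index=man.index, dtype=object))))
    by_home: dict[str, list[str]] = {}
    # only distal probes can survive the >=2 kb filter; recompute distal status
    from .differential import select_distal_probes  # local import to avoid cycle at module load

    distal = select_distal_probes(manifest, annotation)
    for p in probes:
        if p in distal and isinstance(home.get(p), str):
            by_home.setdefault(home[p], []).append(p)

    probe_gene: dict[str, str] = {}
    dm_hypo, dm_hyper = [], []
    for g in demg_genes:
        cand = by_home.get(g, [])[: config.probes_per_demg]
        if not cand:
            logger.warning("planted gene %s has no distal probe; it cannot become a DEMG", g)
        for p in cand:
            probe_gene[p] = g
            (dm_hypo if direction_of[g] == "hypo" else dm_hyper).append(p)

    concentration = 20.0
    mu_bg = rng.uniform(0.3, 0.7, size=len(probes))
    beta_noise_sd = 0.3
    betas = np.empty((len(probes), n_s))

    gh_nodes, gh_weights = np.polynomial.hermite_e.hermegauss(41)
    gh_weights = gh_weights / gh_weights.sum()
    loc_cache: dict[tuple[float, float], float] = {}

    def _logit_loc_scalar(m: float, sigma: float) -> float:
        # calibrate the logistic-normal location so E[expit(loc + sigma Z)]
        # equals the planted group mean m (Gauss-Hermite quadrature)
        key = (round(m, 9), round(sigma, 9))
        if key not in loc_cache:
            f = lambda loc: float(gh_weights @ expit(loc + sigma * gh_nodes)) - m
            loc_cache[key] = brentq(f, -30.0, 30.0)
        return loc_cache[key]

    def _logit_loc(target_mean: np.ndarray, sigma: float) -> np.ndarray:
        return np.array([_logit_loc_scalar(float(m), sigma) for m in target_mean])

    for j, p in enumerate(probes):
        if p in probe_gene:
            g = probe_gene[p]
            if direction_of[g] == "hypo":
                m_norm, m_tum = 0.65, 0.65 - config.planted_delta_beta
                sign = -1.0
            else:
                m_norm, m_tum = 0.35, 0.35 + config.planted_delta_beta
                sign = +1.0
            mu_row = np.where(is_tumor, m_tum, m_norm)
            mname = gene_module.get(g)
            loading = config.factor_loading_meth if mname is not None else 0.0
            sigma = math.sqrt(loading**2 + beta_noise_sd**2)
            x = _logit_loc(mu_row, sigma)
            if mname is not None:
                x = x + sign * loading * factors[mname]
            x = x + beta_noise_sd * rng.standard_normal(n_s)
            betas[j] = expit(x)
        else:
            a = mu_bg[j] * concentration
            b = (1.0 - mu_bg[j]) * concentration
            betas[j] = rng.beta(a, b, size=n_s)
    betas = pd.DataFrame(np.clip(betas, 0.0, 1.0), index=probes, columns=samples)

    # --- somatic mutations --------------------------------------------------
    records = []
    tumor_samples = [s for s, t in zip(samples, is_tumor) if t]
    for s in tumor_samples:
        for g in config.mutated_genes:
            if rng.random() < config.mutation_rate_planted:
                records.append((s, g, VARIANT_CLASSES[rng.choice(4, p=_VARIANT_PROBS)]))
        k = rng.poisson(config.background_mutations_per_patient)
        for gi in rng.integers(0, len(genes), size=k):
            records.append((s, genes[gi], VARIANT_CLASSES[rng.choice(4, p=_VARIANT_PROBS)]))
    mutations = pd.DataFrame(
        records, columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
    )

    # --- clinical + survival ------------------------------------------------
    early = rng.random(n_t) < config.untreated_early_fraction
    stage = np.empty(n_t, dtype=object)
    treated = np.zeros(n_t, dtype=bool)
    for i in range(n_t):
        if early[i]:
            stage[i] = rng.choice(["I", "II"])
        else:
            treated[i] = rng.random() < 0.5
            stage[i] = rng.choice(["I", "II"]) if treated[i] else rng.choice(["III", "IV"])

    burden = np.zeros(n_t)
    if config.prognostic_genes and config.hazard_beta != 0.0:
        comps = []
        tum_counts = counts.values[:, :n_t]
        mut_by_gene = mutations.groupby("Hugo_Symbol")["Tumor_Sample_Barcode"].apply(set)
        for g, sign in config.prognostic_genes.items():
            logc = np.log2(tum_counts[gene_index[g]] + 1.0)
            span = logc.max() - logc.min()
            e = (logc - logc.min()) / span if span > 0 else np.zeros(n_t)
            gp = [p for p, gg in probe_gene.items() if gg == g]
            b = betas.loc[gp, tumor_samples].mean(axis=0).values if gp else np.zeros(n_t)
            mset = mut_by_gene.get(g, set())
            m = np.array([1.0 if s in mset else 0.0 for s in tumor_samples])
            comps.append(sign * (0.5 * e + 0.3 * b + 0.2 * m))
        burden = np.mean(comps, axis=0)
        sd = burden.std()
        burden = (burden - burden.mean()) / sd if sd > 0 else np.zeros(n_t)

    lam0 = math.log(2.0) / config.median_survival_days
    lam = lam0 * np.exp(config.hazard_beta * burden)
    t_event = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        horizon = rng.uniform(0.0, _censoring_horizon(config.censor_rate, lam0), size=n_t)
    else:
        horizon = np.full(n_t, np.inf)
    dead = t_event <= horizon
    obs_time = np.ceil(np.minimum(t_event, horizon)) + 1.0

    clin_rows = []
    for i, s in enumerate(tumor_samples):
        clin_rows.append(
            {
                "sample": s,
                "vital_status": "dead" if dead[i] else "alive",
                "days_to_death": obs_time[i] if dead[i] else np.nan,
                "days_to_last_followup": np.nan if dead[i] else obs_time[i],
                "stage": stage[i],
                "treated": bool(treated[i]),
            }
        )
    for s in samples[n_t:]:
        clin_rows.append(
            {
                "sample": s,
                "vital_status": "alive",
                "days_to_death": np.nan,
                "days_to_last_followup": float(rng.integers(100, 2000)),
                "stage": "NA",
                "treated": False,
            }
        )
    clinical = pd.DataFrame(clin_rows).set_index("sample").loc[samples]

    cohort = MultiOmicsCohort(counts, betas, mutations, clinical, group, cancer_type)
    truth = PlantedTruth(
        de_genes=tuple(de_genes),
        dm_probes_hypo=tuple(dm_hypo),
        dm_probes_hyper=tuple(dm_hyper),
        module_genes={spec.name: tuple(spec.genes) for spec in config.module_spec},
        module_direction={spec.name: spec.direction for spec in config.module_spec},
        prognostic_genes=dict(config.prognostic_genes),
        mutated_genes=tuple(config.mutated_genes),
        probe_gene=dict(probe_gene),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# splitting & comparability
# ---------------------------------------------------------------------------

def split_cohort(
    cohort: MultiOmicsCohort, fraction: float, seed: int = 0
) -> tuple[MultiOmicsCohort, MultiOmicsCohort]:
    """Random split into train/validation, stratified by tumor/normal group."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, val = [], []
    for label in ("tumor", "normal"):
        members = [s for s in cohort.samples if cohort.group[s] == label]
        if not members:
            raise ValueError(f"group '{label}' absent from cohort")
        order = rng.permutation(len(members))
        k = int(round(fraction * len(members)))
        if k == 0 or k == len(members):
            raise ValueError(f"fraction {fraction} empties group '{label}' in one split")
        train.extend(members[i] for i in order[:k])
        val.extend(members[i] for i in order[k:])
    keep_order = lambda chosen: [s for s in cohort.samples if s in set(chosen)]
    return cohort.subset(keep_order(train)), cohort.subset(keep_order(val))


def chi_square_comparability(
    train_clinical: pd.DataFrame, val_clinical: pd.DataFrame, variable: str
) -> tuple[float, float]:
    """Pearson chi-square on the ``variable x split`` contingency table.

    Uses the uncorrected statistic (no continuity correction).  A variable
    with a single observed category is degenerate and reported as (0, 1).
    """
    for name, tab in (("train", train_clinical), ("validation", val_clinical)):
        if variable not in tab.columns:
            raise KeyError(f"variable '{variable}' absent from {name} table")
        if len(tab) == 0:
            raise ValueError(f"{name} clinical table is empty")
    a = train_clinical[variable].value_counts()
    b = val_clinical[variable].value_counts()
    cats = sorted(set(a.index) | set(b.index))
    if len(cats) < 2:
        logger.warning("variable '%s' has a single category; chi-square degenerate", variable)
        return 0.0, 1.0
    obs = np.array([[a.get(c, 0) for c in cats], [b.get(c, 0) for c in cats]])
    stat, p, _, _ = chi2_contingency(obs, correction=False)
    return float(stat), float(p)
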