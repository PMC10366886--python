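import dataclasses

import numpy as np
import pandas as pd
import pytest

from netomics.synthetic import (CohortConfig, GenomeAnnotation, ModuleSpec,
                                ProbeManifest, default_cohort_config,
                                generate_annotation, generate_cohort)


@pytest.fixture(scope="session")
def small_genome():
    """50-gene / 100-probe genome shared by unit tests."""
    return generate_annotation(50, 100, seed=7)


@pytest.fixture(scope="session")
def default_genome():
    """The full study genome (1000 genes / 2000 probes)."""
    return generate_annotation(1000, 2000, seed=1)


def small_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Scaled-down study conditions over a 300-gene genome (75 genes per
    chromosome): two hypo modules, one hyper module, background DEMGs and
    buffer blocks laid out like the default genome."""
    gid = lambda i: f"G{i:04d}"
    rg = lambda a, b: tuple(gid(i) for i in range(a, b))
    cfg = CohortConfig(
        n_tumor=70,
        n_normal=24,
        n_genes=300,
        n_probes=600,
        module_spec=(
            ModuleSpec("S1", rg(0, 8), "hypo"),
            ModuleSpec("S2", rg(75, 83), "hypo"),
            ModuleSpec("S3", rg(150, 157), "hyper"),
        ),
        demg_background=(
            ModuleSpec("bg_hypo", rg(20, 30) + rg(95, 105), "hypo"),
            ModuleSpec("bg_hyper", rg(170, 178), "hyper"),
        ),
        de_only_genes=rg(8, 16) + rg(83, 91) + rg(157, 165) + rg(225, 235),
        prognostic_genes={gid(i): +1 for i in range(0, 3)},
        mutated_genes=rg(0, 3) + rg(240, 244),
        seed=seed,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


@pytest.fixture(scope="session")
def small_multiomics():
    """One small generated cohort plus its planted truth."""
    ann, man = generate_annotation(300, 600, seed=3)
    cohort, truth = generate_cohort(small_cohort_config(seed=3), ann, man, "SYN")
    return ann, man, cohort, truth


@pytest.fixture
def toy_annotation():
    """Hand-placed genes for distance logic tests."""
    table = pd.DataFrame(
        {
            "gene_id": ["A", "B", "C"],
            "chromosome": ["chr1", "chr1", "chr2"],
            "tss": [10_000, 50_000, 30_000],
            "strand": ["+", "-", "+"],
        }
    )
    return GenomeAnnotation(table)


def make_manifest(rows):
    return ProbeManifest(pd.DataFrame(rows, columns=["probe_id", "chromosome", "position"]))
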