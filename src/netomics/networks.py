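"""Normalized-correlation gene networks.

Co-expression and co-methylation networks are built from per-gene profiles
with the same recipe: Pearson correlation r_ij for every gene pair, Fisher
z transform z = atanh(r), standardization of the off-diagonal z values to
z' = (z - mu) / sigma, inverse Fisher transform r' = tanh(z'), and finally
|r'| as the edge weight.  Standardizing on the z scale makes correlation
estimates comparable between datasets of different sample sizes before they
are fused.

mu and sigma are computed over the off-diagonal upper triangle (each pair
counted once) with the sample (n-1) standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_R_CLIP = 1.0 - 1e-7  # atanh diverges at |r| = 1


@dataclass(frozen=True)
class CorrelationMatrix:
    genes: tuple[str, ...]
    r: np.ndarray  # symmetric, diagonal 1, values in [-1, 1]


@dataclass(frozen=True)
class NormalizedCorrelation:
    genes: tuple[str, ...]
    z: np.ndarray
    mu: float
    sigma: float
    z_std: np.ndarray
    r_norm: np.ndarray  # tanh(z_std), in (-1, 1)
    degenerate: bool = False


@dataclass(frozen=True)
class GeneNetwork:
    """Symmetric weighted gene-gene adjacency, weights in [0, 1], zero diagonal."""

    genes: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        w = self.weights
        if w.shape != (len(self.genes), len(self.genes)):
            raise ValueError("weight matrix shape does not match gene list")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if (w < 0).any() or (w > 1).any():
            raise ValueError("weights must lie in [0, 1]")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.genes), columns=list(self.genes))


def pairwise_correlation(profiles: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlation over samples for every gene pair.

    ``profiles`` is genes x samples.  Constant gene rows yield correlation 0
    with every partner (flagged with a warning) rather than NaN.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    x = profiles.values.astype(float)
    sd = x.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning("%d constant gene profiles; their correlations set to 0",
                       int(const.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(tuple(profiles.index), r)


def fisher_z(r):
    """Fisher z transform, z = 0.5 ln((1+r)/(1-r)), with r clipped to
    +/-(1 - 1e-7)."""
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def inverse_fisher(z):
    """Inverse Fisher transform, (exp(2z) - 1)/(exp(2z) + 1) = tanh(z)."""
    return np.tanh(z)


def normalize_correlations(R: CorrelationMatrix) -> NormalizedCorrelation:
    """Standardize Fisher-transformed correlations over the off-diagonal
    upper triangle; sigma = 0 is a degenerate input and maps everything to
    r' = 0 (flagged)."""
    n = len(R.genes)
    z = fisher_z(R.r)
    iu = np.triu_indices(n, k=1)
    mu = float(np.mean(z[iu]))
    sigma = float(np.std(z[iu], ddof=1)) if len(iu[0]) > 1 else 0.0
    if sigma == 0.0:
        logger.warning("degenerate correlation matrix (sigma = 0); all r' set to 0")
        z_std = np.zeros_like(z)
    else:
        z_std = (z - mu) / sigma
    r_norm = inverse_fisher(z_std)
    return NormalizedCorrelation(R.genes, z, mu, sigma, z_std, r_norm, degenerate=sigma == 0.0)


def build_network(N: NormalizedCorrelation) -> GeneNetwork:
    """Edge weights |r'| with a zero diagonal."""
    w = np.abs(N.r_norm).astype(float)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return GeneNetwork(N.genes, np.clip(w, 0.0, 1.0))


def correlation_network(profiles: pd.DataFrame) -> GeneNetwork:
    """The full recipe in one call: Pearson -> Fisher z -> standardize ->
    inverse -> absolute value."""
    return build_network(normalize_correlations(pairwise_correlation(profiles)))
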