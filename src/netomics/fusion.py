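"""Similarity network fusion (SNF) of the co-expression and co-methylation
gene networks.

SNF iteratively diffuses each layer's similarity through the other layer's
K-nearest-neighbour graph, strengthening edges supported by both layers as
well as very strong single-layer edges.  The inputs here are already
similarities (absolute normalized correlations in [0, 1]), so the usual
distance-to-affinity kernel -- where the alpha hyper-parameter would act --
is skipped; alpha is accepted for interface parity but inert.

Defaults K = 9 neighbours and t = 20 iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .networks import GeneNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SNFParams:
    K: int = 9
    t: int = 20
    alpha: float | None = None  # inert; kept for interface parity

    def validate(self, n: int) -> None:
        if self.K < 1 or self.K >= n:
            raise ValueError(f"K must satisfy 1 <= K < n (K={self.K}, n={n})")
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if self.alpha is not None:
            warnings.warn(
                "alpha is inert: inputs are already similarities, so the "
                "distance-to-affinity kernel is not applied",
                stacklevel=2,
            )


def full_kernel(W: np.ndarray) -> np.ndarray:
    """Row-stochastic full kernel: P(i,j) = W(i,j) / (2 sum_{k != i} W(i,k))
    off-diagonal and P(i,i) = 1/2.  Zero rows fall back to a uniform
    off-diagonal distribution (flagged)."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1)
    zero = rowsum == 0
    if zero.any():
        logger.warning("%d zero rows in full_kernel; uniform fallback", int(zero.sum()))
    P = np.empty_like(off)
    safe = np.where(zero, 1.0, rowsum)
    P[:] = off / (2.0 * safe[:, None])
    if zero.any() and n > 1:
        P[zero, :] = 0.5 / (n - 1)
    np.fill_diagonal(P, 0.5)
    return P


def local_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """KNN-sparsified row-normalized kernel: keep each row's K largest
    off-diagonal weights (ties by column order), normalize to sum 1."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not (1 <= K < n):
        raise ValueError(f"K must satisfy 1 <= K < n (K={K}, n={n})")
    S = np.zeros_like(W)
    for i in range(n):
        row = W[i].copy()
        row[i] = -np.inf
        # stable top-K: sort by (-weight, column index)
        order = np.lexsort((np.arange(n), -row))
        nbrs = order[:K]
        total = W[i, nbrs].sum()
        if total == 0:
            S[i, nbrs] = 1.0 / K
        else:
            S[i, nbrs] = W[i, nbrs] / total
    return S


def minmax_normalize(W: np.ndarray) -> np.ndarray:
    """Min-max normalize over off-diagonal entries; constant matrices map to
    all zeros (flagged).  The diagonal is zeroed."""
    W = np.asarray(W, dtype=float).copy()
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    lo, hi = W[iu].min(), W[iu].max()
    if hi == lo:
        logger.warning("constant off-diagonal in min-max normalization; all zeros")
        out = np.zeros_like(W)
    else:
        out = (W - lo) / (hi - lo)
    np.fill_diagonal(out, 0.0)
    return np.clip((out + out.T) / 2.0, 0.0, 1.0)


def _stabilize(P: np.ndarray) -> np.ndarray:
    """Re-symmetrize and regularize the diagonal after a diffusion step.

    Adding the identity keeps self-similarity dominant and the iteration
    numerically stable; renormalizing rows here instead would suppress
    exactly the strong edges the fusion is meant to reinforce.
    """
    P = (P + P.T) / 2.0
    return P + np.eye(P.shape[0])


def snf_fuse(
    w_expr: GeneNetwork, w_meth: GeneNetwork, params: SNFParams = SNFParams()
) -> GeneNetwork:
    """Fuse two gene networks into one integrated similarity network.

    Both matrices are restricted to the common gene set, diffused for
    ``params.t`` iterations with simultaneous updates
    P1 <- S1 P2 S1^T, P2 <- S2 P1 S2^T (each step re-symmetrized with an
    identity regularization), averaged, kernel-normalized once, and min-max
    normalized with a zero diagonal.
    """
    common = [g for g in w_expr.genes if g in set(w_meth.genes)]
    if not common:
        raise ValueError("no genes common to the two networks")
    params.validate(len(common))

    def restrict(net: GeneNetwork) -> np.ndarray:
        idx = [net.genes.index(g) for g in common]
        return net.weights[np.ix_(idx, idx)]

    W1, W2 = restrict(w_expr), restrict(w_meth)
    P1, P2 = full_kernel(W1), full_kernel(W2)
    # gene networks have zero diagonals, so the raw KNN kernel carries no
    # self-transition mass and the diffusion would reward only two-hop
    # paths, inverting edge rankings; keeping half the mass on the node
    # itself restores the direct-edge reinforcement of the reference scheme
    eye = np.eye(len(common))
    S1 = (local_kernel(W1, params.K) + eye) / 2.0
    S2 = (local_kernel(W2, params.K) + eye) / 2.0

    for _ in range(params.t):
        P1_new = S1 @ P2 @ S1.T
        P2_new = S2 @ P1 @ S2.T
        P1, P2 = _stabilize(P1_new), _stabilize(P2_new)
        if np.isnan(P1).any() or np.isnan(P2).any():
            raise FloatingPointError("SNF iteration produced NaN; check the input networks")

    fused = (P1 + P2) / 2.0
    fused = full_kernel(fused)
    fused = (fused + fused.T) / 2.0
    fused = minmax_normalize(fused)
    return GeneNetwork(tuple(common), fused)
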