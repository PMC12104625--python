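"""Gene importance scores from an out-degree-oriented PageRank, and feature fusion.

Classical PageRank rewards pages that many pages link *to*. For regulatory
networks the interesting genes are the regulators, so the random surfer here
follows edges backwards: a gene scores high when it regulates many genes, or
regulates genes that are themselves important. Formally, the transition matrix

    M*[i, j] = 1 / out_degree(j)   if the edge j -> i exists, else 0

distributes gene j's importance evenly over the genes it regulates, and the
score vector is iterated as

    v' = beta * M* @ v + (1 - beta) / n

with damping factor ``beta`` (default 0.85). This is exactly classical
PageRank run on the edge-reversed graph.

Genes with no outgoing edges ("dangling" regulatorless genes) would leak score
mass; their columns are replaced by the uniform vector during iteration so
that the scores stay a probability distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import DirectedGRN, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class TransitionMatrix:
    """Column-substochastic transition matrix M* of the reversed-edge walk."""

    M_star: sp.csr_matrix
    dangling: np.ndarray  # boolean mask of genes with out-degree 0

    @property
    def n(self) -> int:
        return self.M_star.shape[0]


@dataclass
class ImportanceScores:
    """PageRank-style importance score per gene; sums to 1 after dangling correction."""

    v: np.ndarray
    beta: float
    iterations_run: int
    converged: bool


def build_transition_matrix(grn: DirectedGRN) -> TransitionMatrix:
    """M*[i, j] = 1/out_degree(j) if j regulates i, else 0."""
    out_deg = grn.out_degrees().astype(float)
    A = grn.adjacency  # A[j, i] = 1 iff j -> i
    with np.errstate(divide="ignore"):
        inv = np.where(out_deg > 0, 1.0 / np.maximum(out_deg, 1.0), 0.0)
    # scale row j of A by 1/out_deg(j), then transpose: entry (i, j) = A[j, i]/deg(j)
    M = sp.diags(inv) @ A
    return TransitionMatrix(M_star=sp.csr_matrix(M.T), dangling=out_deg == 0)


def pagerank_star(
    transition: TransitionMatrix,
    beta: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 200,
    dangling_correction: bool = True,
) -> ImportanceScores:
    """Power-iterate v' = beta * M* v + (1 - beta) e / n from the uniform vector.

    Stops when the L1 change drops below ``tol``. With ``dangling_correction``
    the score mass of out-degree-0 genes is redistributed uniformly each step,
    keeping sum(v) == 1.
    """
    if not 0 < beta < 1:
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = transition.n
    M = transition.M_star
    dangling = transition.dangling
    v = np.full(n, 1.0 / n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        v_new = beta * (M @ v) + (1.0 - beta) / n
        if dangling_correction and dangling.any():
            v_new += beta * v[dangling].sum() / n
        if np.abs(v_new - v).sum() < tol:
            v = v_new
            converged = True
            break
        v = v_new
    if not converged:
        logger.warning("pagerank_star did not converge in %d iterations", max_iter)
    return ImportanceScores(v=v, beta=beta, iterations_run=it, converged=converged)


def importance_scores(
    grn: DirectedGRN,
    beta: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 200,
    orientation: str = "regulator",
) -> ImportanceScores:
    """Gene-importance scores for a regulatory network.

    With ``orientation="regulator"`` (default) the propagation runs on the
    edge-reversed network, so score mass flows from targets back to their
    regulators: a gene regulating many genes — or regulating important genes —
    scores high. This is the out-degree-oriented reading and equals classical
    PageRank on the reversed graph. ``orientation="target"`` propagates along
    the regulatory edges as drawn, rewarding heavily regulated genes instead.
    """
    if orientation not in ("regulator", "target"):
        raise ValueError("orientation must be 'regulator' or 'target'")
    graph = grn.reverse() if orientation == "regulator" else grn
    return pagerank_star(
        build_transition_matrix(graph), beta=beta, tol=tol, max_iter=max_iter
    )


def call_important_genes(grn: DirectedGRN, threshold: int = 7) -> set[int]:
    """Genes regulating at least ``threshold`` targets (hub regulators)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return set(np.flatnonzero(grn.out_degrees() >= threshold).tolist())


def fuse_expression(
    scores: ImportanceScores, T: ExpressionMatrix, alpha: float = 0.1
) -> np.ndarray:
    """X = alpha * PBM + (1 - alpha) * T, broadcasting each gene's score over cells."""
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if scores.v.shape[0] != T.n_genes:
        raise ValueError(
            f"score length {scores.v.shape[0]} != gene count {T.n_genes}"
        )
    pbm = np.repeat(scores.v[:, None], T.cell_count, axis=1)
    return alpha * pbm + (1.0 - alpha) * T.values


def rescale_scores(v: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance rescaling; all-equal scores map to zeros."""
    sd = v.std()
    if sd < 1e-12:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def fuse_mass(
    scores: ImportanceScores,
    m_tilde: np.ndarray,
    alpha: float = 0.1,
    rescale: bool = True,
) -> np.ndarray:
    """m' = alpha * scores + (1 - alpha) * m_tilde, elementwise.

    Raw scores sum to 1 and so are O(1/n) while the learned masses are
    unbounded; by default the scores are standardized first so the fusion term
    is not numerically inert at large n. ``rescale=False`` gives the raw form.
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    m_tilde = np.asarray(m_tilde, dtype=float)
    if scores.v.shape != m_tilde.shape:
        raise ValueError(
            f"shape mismatch: scores {scores.v.shape} vs masses {m_tilde.shape}"
        )
    s = rescale_scores(scores.v) if rescale else scores.v
    return alpha * s + (1.0 - alpha) * m_tilde
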