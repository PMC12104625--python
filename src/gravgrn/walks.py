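"""Random-walk regularization: node2vec walks and a Skip-Gram objective on Z'.

Graph autoencoders tend to produce unevenly distributed latent vectors; nodes
that are structurally close in the network can land far apart in latent
space. The regularizer counters this by (1) sampling second-order biased
random walks (node2vec) over the training network, (2) treating nodes that
co-occur within a window of a walk as (center, context) pairs, and
(3) adding a negative-sampling Skip-Gram loss on the fused per-gene vectors
Z' = [Z | m'], whose gradient flows back into the encoder weights.

Walks traverse edges bidirectionally by default: in a regulatory network most
genes are pure targets (sinks), so strictly directed walks die after one hop
and yield an empty corpus. ``directed=True`` preserves strict direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .io import DirectedGRN


@dataclass
class WalkCorpus:
    walks: list[list[int]]
    walk_length: int
    walks_per_node: int
    p: float
    q: float


def _neighbor_sets(grn: DirectedGRN, directed: bool) -> list[np.ndarray]:
    nbrs: list[set[int]] = [set() for _ in range(grn.n_genes)]
    for i, j in grn.edges:
        if i == j:
            continue
        nbrs[i].add(j)
        if not directed:
            nbrs[j].add(i)
    return [np.array(sorted(s), dtype=int) for s in nbrs]


def generate_walks(
    grn: DirectedGRN,
    length: int = 9,
    per_node: int = 5,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 0,
    directed: bool = False,
) -> WalkCorpus:
    """Second-order node2vec walks over the (by default bidirectional) train graph.

    Unnormalized step weights relative to the previous node ``t``: 1/p to
    return to ``t``, 1 to a neighbor of ``t`` (breadth-first-like), 1/q to a
    node two hops from ``t`` (depth-first-like). Walks truncate at sinks;
    every node with at least one neighbor starts ``per_node`` walks.
    """
    if length < 1 or per_node < 1:
        raise ValueError("length and per_node must be >= 1")
    if p <= 0 or q <= 0:
        raise ValueError("p and q must be positive")
    rng = np.random.default_rng(seed)
    nbrs = _neighbor_sets(grn, directed)
    nbr_sets = [set(a.tolist()) for a in nbrs]
    walks: list[list[int]] = []
    for _ in range(per_node):
        for start in range(grn.n_genes):
            walk = [start]  # isolated nodes yield length-1 walks
            while len(walk) < length:
                cur = walk[-1]
                cand = nbrs[cur]
                if len(cand) == 0:
                    break  # sink: truncate early
                if len(walk) == 1 or (p == 1.0 and q == 1.0):
                    nxt = cand[rng.integers(len(cand))]
                else:
                    prev = walk[-2]
                    w = np.where(
                        cand == prev,
                        1.0 / p,
                        np.where([c in nbr_sets[prev] for c in cand], 1.0, 1.0 / q),
                    )
                    w = w / w.sum()
                    nxt = cand[rng.choice(len(cand), p=w)]
                walk.append(int(nxt))
            walks.append(walk)
    return WalkCorpus(walks=walks, walk_length=length, walks_per_node=per_node, p=p, q=q)


def skipgram_pairs(corpus: WalkCorpus, window: int = 3, exclude_self: bool = True) -> np.ndarray:
    """All ordered (center, context) pairs within ``window`` positions in any walk.

    Bidirectional walks can bounce back and forth across one edge, putting the
    same node at two positions within a window; the resulting degenerate
    (a, a) pairs carry no similarity information and only inflate embedding
    norms, so they are dropped by default.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    pairs: list[tuple[int, int]] = []
    for walk in corpus.walks:
        L = len(walk)
        for t in range(L):
            lo, hi = max(0, t - window), min(L, t + window + 1)
            for u in range(lo, hi):
                if u != t and not (exclude_self and walk[u] == walk[t]):
                    pairs.append((walk[t], walk[u]))
    if not pairs:
        return np.empty((0, 2), dtype=int)
    return np.asarray(pairs, dtype=int)


def sample_negatives(
    n_nodes: int,
    n_pairs: int,
    negatives_per_pair: int,
    rng: np.random.Generator,
    corpus: WalkCorpus | None = None,
    unigram_exponent: float = 0.75,
) -> np.ndarray:
    """Noise nodes for negative sampling, shape (n_pairs, negatives_per_pair).

    With a ``corpus`` given, negatives follow the corpus unigram distribution
    raised to ``unigram_exponent`` (the word2vec standard), so nodes that
    never occur in a walk are never used as noise; without one, negatives are
    uniform over all nodes.
    """
    if corpus is None:
        return rng.integers(0, n_nodes, size=(n_pairs, negatives_per_pair))
    counts = np.zeros(n_nodes)
    for walk in corpus.walks:
        np.add.at(counts, walk, 1.0)
    weights = counts**unigram_exponent
    total = weights.sum()
    if total == 0:
        return rng.integers(0, n_nodes, size=(n_pairs, negatives_per_pair))
    return rng.choice(
        n_nodes, size=(n_pairs, negatives_per_pair), p=weights / total
    )


def skipgram_loss_grads(
    Z_prime: np.ndarray,
    pairs: np.ndarray,
    negatives: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Negative-sampling Skip-Gram loss and its gradient w.r.t. Z'.

    loss = -mean over pairs [ log sigmoid(z'_c . z'_ctx)
                              + sum_neg log sigmoid(-z'_c . z'_neg) ]

    Returns ``(loss, grad)`` with ``grad`` the same shape as ``Z_prime``.
    An empty pair list yields loss 0 (with a warning) and a zero gradient.
    """
    grad = np.zeros_like(Z_prime)
    if len(pairs) == 0:
        warnings.warn("empty Skip-Gram batch; loss defined as 0")
        return 0.0, grad
    c, ctx = pairs[:, 0], pairs[:, 1]
    B = len(pairs)

    s_pos = np.einsum("ij,ij->i", Z_prime[c], Z_prime[ctx])
    loss = np.logaddexp(0.0, -s_pos).sum()
    # d(-log sigmoid(s))/ds = sigmoid(s) - 1
    g_pos = (expit(s_pos) - 1.0) / B
    np.add.at(grad, c, g_pos[:, None] * Z_prime[ctx])
    np.add.at(grad, ctx, g_pos[:, None] * Z_prime[c])

    if negatives is not None and negatives.size:
        k = negatives.shape[1]
        neg = negatives.ravel()
        c_rep = np.repeat(c, k)
        s_neg = np.einsum("ij,ij->i", Z_prime[c_rep], Z_prime[neg])
        loss += np.logaddexp(0.0, s_neg).sum()
        g_neg = expit(s_neg) / B
        np.add.at(grad, c_rep, g_neg[:, None] * Z_prime[neg])
        np.add.at(grad, neg, g_neg[:, None] * Z_prime[c_rep])

    return float(loss / B), grad


def pair_count_matrices(
    pairs: np.ndarray, negatives: np.ndarray | None, n_nodes: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Multiplicity matrices for the aggregated Skip-Gram computation.

    ``W_pos[a, b]`` counts occurrences of (center=a, context=b) in the corpus,
    ``W_neg[a, b]`` occurrences of (center=a, negative=b). Because the walk
    corpus and negatives are fixed across a training run, the per-pair loss
    collapses to dense sums weighted by these counts (see
    :func:`skipgram_loss_grads_aggregated`).
    """
    W_pos = np.zeros((n_nodes, n_nodes))
    W_neg = np.zeros((n_nodes, n_nodes))
    B = len(pairs)
    if B:
        flat = pairs[:, 0] * n_nodes + pairs[:, 1]
        W_pos += np.bincount(flat, minlength=n_nodes * n_nodes).reshape(n_nodes, n_nodes)
    if negatives is not None and negatives.size:
        c_rep = np.repeat(pairs[:, 0], negatives.shape[1])
        flat = c_rep * n_nodes + negatives.ravel()
        W_neg += np.bincount(flat, minlength=n_nodes * n_nodes).reshape(n_nodes, n_nodes)
    return W_pos, W_neg, B


def skipgram_loss_grads_aggregated(
    Z_prime: np.ndarray, W_pos: np.ndarray, W_neg: np.ndarray, n_pairs: int
) -> tuple[float, np.ndarray]:
    """Exactly :func:`skipgram_loss_grads`, computed from pair-count matrices.

    Uses the Gram matrix S = Z' Z'^T so the cost is O(n^2 d) per call instead
    of O(|corpus| d); agrees with the per-pair route to float tolerance.
    """
    if n_pairs == 0:
        return 0.0, np.zeros_like(Z_prime)
    S = Z_prime @ Z_prime.T
    loss = (W_pos * np.logaddexp(0.0, -S)).sum() + (W_neg * np.logaddexp(0.0, S)).sum()
    C = W_pos * (expit(S) - 1.0) + W_neg * expit(S)
    grad = ((C + C.T) @ Z_prime) / n_pairs
    return float(loss / n_pairs), grad
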