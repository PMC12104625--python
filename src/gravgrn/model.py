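"""Gravity-inspired graph autoencoder for directed edge prediction.

The encoder is a two-layer graph convolution on the out-degree-normalized
adjacency ``A~ = D_out^{-1}(A + I)``:

    H = relu(A~ X W1),    [Z | m~] = A~ H W2

producing, per gene, a d-dimensional latent vector ``z_i`` and a scalar mass
``m~_i``. The decoder scores a directed edge i -> j by a log-transformed
Newtonian acceleration of i towards j:

    score(i -> j) = sigmoid( m'_j - log(||z_i - z_j||^2 + eps) )

The mass of the *target* carries all of the directionality: a gene with a
large mass attracts edges pointing at it, while the squared latent distance
is symmetric. Setting all masses to a shared constant collapses the decoder
to a symmetric (undirected) graph autoencoder, which is the GAE ablation
baseline.

Everything here is plain numpy with analytic gradients; the gradient of every
loss with respect to the encoder weights is exposed so a random-walk
regularizer can add its own term to the same backward pass (see
:mod:`gravgrn.walks`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import expit

from .io import DirectedGRN

EPS = 1e-8  # guard inside the log: squared distances can be exactly 0

#: above this many genes the propagation matrix is kept sparse
DENSE_N_THRESHOLD = 2000


def normalize_adjacency(grn: DirectedGRN):
    """A~ = D_out^{-1}(A + I): add self-loops, divide each row by its out-degree.

    Every row sums to 1 and the diagonal is strictly positive (the self-loop
    guarantees a nonzero row sum). Returns a dense array for small graphs and
    a CSR matrix above :data:`DENSE_N_THRESHOLD` genes; results agree to
    float tolerance.
    """
    n = grn.n_genes
    A = grn.adjacency.tolil()
    A.setdiag(1.0)
    A = sp.csr_matrix(A)
    row_sums = np.asarray(A.sum(axis=1)).ravel()
    A_tilde = sp.diags(1.0 / row_sums) @ A
    if n <= DENSE_N_THRESHOLD:
        return A_tilde.toarray()
    return sp.csr_matrix(A_tilde)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass
class EncoderCache:
    """Intermediate activations kept for the backward pass."""

    AX: np.ndarray      # A~ X
    H_pre: np.ndarray   # A~ X W1
    H: np.ndarray       # relu(H_pre)
    AH: np.ndarray      # A~ H
    out: np.ndarray     # A~ H W2  -> [Z | m~]


@dataclass
class GravityGAE:
    """Two-layer GCN encoder with a gravity decoder.

    Parameters
    ----------
    n_features:
        Width of the per-gene input feature vectors (number of cells).
    hidden_dim, latent_dim:
        Hidden layer width H and latent dimension d; the encoder output is
        d + 1 wide, the last column being the mass.
    seed:
        Seeds the Glorot-uniform weight initialization.
    """

    n_features: int
    hidden_dim: int = 256
    latent_dim: int = 256
    seed: int = 0
    W1: np.ndarray = field(init=False)
    W2: np.ndarray = field(init=False)

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        self.W1 = glorot_uniform(rng, self.n_features, self.hidden_dim)
        self.W2 = glorot_uniform(rng, self.hidden_dim, self.latent_dim + 1)

    # -- forward ---------------------------------------------------------

    def encode(self, A_tilde, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, EncoderCache]:
        """Return (Z, m~, cache). Z is n x d; m~ is the length-n mass vector."""
        AX = A_tilde @ X
        H_pre = AX @ self.W1
        H = np.maximum(H_pre, 0.0)
        AH = A_tilde @ H
        out = AH @ self.W2
        if not np.isfinite(out).all():
            layer = "1" if not np.isfinite(H).all() else "2"
            raise FloatingPointError(f"non-finite activations in encoder layer {layer}")
        cache = EncoderCache(AX=AX, H_pre=H_pre, H=H, AH=AH, out=out)
        return out[:, : self.latent_dim], out[:, self.latent_dim], cache

    def backward(self, A_tilde, cache: EncoderCache, grad_out: np.ndarray):
        """Gradients of a scalar loss w.r.t. (W1, W2) given d loss / d out."""
        At = A_tilde.T
        gW2 = cache.AH.T @ grad_out
        gAH = grad_out @ self.W2.T
        gH = At @ gAH
        gH_pre = gH * (cache.H_pre > 0)
        gW1 = cache.AX.T @ gH_pre
        return gW1, gW2

    @property
    def parameters(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "W2": self.W2}


# -- decoder ---------------------------------------------------------------


def pairwise_sq_dists(Z: np.ndarray) -> np.ndarray:
    """Full n x n matrix of squared Euclidean distances between latent rows."""
    sq = np.einsum("ij,ij->i", Z, Z)
    D = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
    return np.maximum(D, 0.0)


def decode_pairs(
    Z: np.ndarray,
    m_prime: np.ndarray,
    pairs,
    symmetric: bool = False,
) -> np.ndarray:
    """Edge scores sigmoid(m'_j - log(||z_i - z_j||^2 + eps)) for (i, j) pairs.

    With ``symmetric=True`` the mass term is dropped (GAE ablation baseline).
    """
    pairs = np.asarray(pairs)
    i, j = pairs[:, 0], pairs[:, 1]
    diff = Z[i] - Z[j]
    d2 = np.einsum("ij,ij->i", diff, diff)
    logits = -np.log(d2 + EPS)
    if not symmetric:
        logits = logits + m_prime[j]
    return expit(logits)


def decode_full(Z: np.ndarray, m_prime: np.ndarray, symmetric: bool = False) -> np.ndarray:
    """Full reconstructed score matrix A^ (entries strictly inside (0, 1))."""
    logits = -np.log(pairwise_sq_dists(Z) + EPS)
    if not symmetric:
        logits = logits + m_prime[None, :]
    return expit(logits)


# -- reconstruction loss ----------------------------------------------------


def reconstruction_loss(scores: np.ndarray, labels: np.ndarray, pos_weight: float = 1.0) -> float:
    """Weighted binary cross-entropy on probabilities (positives up-weighted)."""
    labels = np.asarray(labels, dtype=float)
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    scores = np.clip(np.asarray(scores, dtype=float), 1e-12, 1.0 - 1e-12)
    terms = -(pos_weight * labels * np.log(scores) + (1.0 - labels) * np.log1p(-scores))
    return float(terms.mean())


def bce_full_grads(
    Z: np.ndarray,
    m_prime: np.ndarray,
    adjacency: sp.spmatrix,
    pos_weight: float | None = None,
    symmetric: bool = False,
):
    """BCE over all off-diagonal ordered pairs, with gradients.

    Labels come from the (train) adjacency. Returns
    ``(loss, grad_Z, grad_m_prime)``; ``grad_m_prime`` is zero in symmetric
    mode. Default ``pos_weight`` is the standard GAE ratio
    (#negative pairs / #positive pairs).
    """
    n = Z.shape[0]
    Y = np.asarray(adjacency.todense(), dtype=float)
    np.fill_diagonal(Y, 0.0)
    n_pos = Y.sum()
    n_pairs = n * (n - 1)
    if pos_weight is None:
        pos_weight = (n_pairs - n_pos) / max(n_pos, 1.0)

    D = pairwise_sq_dists(Z)
    logits = -np.log(D + EPS)
    if not symmetric:
        logits = logits + m_prime[None, :]
    off = ~np.eye(n, dtype=bool)

    loss_terms = pos_weight * Y * _softplus(-logits) + (1.0 - Y) * _softplus(logits)
    loss = float(loss_terms[off].sum() / n_pairs)

    sig = expit(logits)
    G = (-pos_weight * Y * (1.0 - sig) + (1.0 - Y) * sig) / n_pairs
    G[~off] = 0.0

    grad_m = np.zeros(n) if symmetric else G.sum(axis=0)
    # d logits / d D = -1/(D + eps); d D_ij/d z_i = 2(z_i - z_j), d D_ij/d z_j = -2(...)
    C = G * (-1.0 / (D + EPS))
    row = C.sum(axis=1)
    col = C.sum(axis=0)
    grad_Z = 2.0 * ((row + col)[:, None] * Z - (C + C.T) @ Z)
    return loss, grad_Z, grad_m


def bce_pairs_grads(
    Z: np.ndarray,
    m_prime: np.ndarray,
    pairs: np.ndarray,
    labels: np.ndarray,
    pos_weight: float = 1.0,
    symmetric: bool = False,
):
    """BCE restricted to an explicit pair list (sampled-negatives training mode)."""
    pairs = np.asarray(pairs)
    labels = np.asarray(labels, dtype=float)
    i, j = pairs[:, 0], pairs[:, 1]
    diff = Z[i] - Z[j]
    d2 = np.einsum("ij,ij->i", diff, diff)
    logits = -np.log(d2 + EPS)
    if not symmetric:
        logits = logits + m_prime[j]
    m = len(labels)
    loss = float(
        (pos_weight * labels * _softplus(-logits) + (1.0 - labels) * _softplus(logits)).sum() / m
    )
    sig = expit(logits)
    g = (-pos_weight * labels * (1.0 - sig) + (1.0 - labels) * sig) / m

    grad_m = np.zeros(Z.shape[0])
    if not symmetric:
        np.add.at(grad_m, j, g)
    gd2 = g * (-1.0 / (d2 + EPS))
    grad_Z = np.zeros_like(Z)
    np.add.at(grad_Z, i, (2.0 * gd2)[:, None] * diff)
    np.add.at(grad_Z, j, (-2.0 * gd2)[:, None] * diff)
    return loss, grad_Z, grad_m


# -- optimizer ---------------------------------------------------------------


class Adam:
    """Standard Adam with bias correction; state keyed by parameter name."""

    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, p in params.items():
            g = grads[name]
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
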