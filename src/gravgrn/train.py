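"""Training orchestration, held-out edge evaluation, and novel-edge ranking.

Model variants (the ablation ladder):

========== =================== ============== ==============
variant     decoder             importance     random-walk
                                fusion (WF)    regularizer
========== =================== ============== ==============
gae         symmetric           off            off
gigae       gravity (directed)  off            off
gigae_wf    gravity             on             off
gigae_rwr   gravity             off            on
full        gravity             on             on
========== =================== ============== ==============

Training minimizes weighted binary cross-entropy between the decoder's
reconstructed scores and the *train* adjacency (plus, when active, the
Skip-Gram regularization term) with Adam. The checkpoint with the best
validation AUROC over the run is returned. Importance scores are computed on
the train network only, never on held-out edges.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import model as M
from . import walks as W
from .importance import fuse_expression, fuse_mass, importance_scores
from .io import DirectedGRN, EdgeSplit, ExpressionMatrix

VARIANTS = ("gae", "gigae", "gigae_wf", "gigae_rwr", "full")


@dataclass
class TrainConfig:
    epochs: int = 100
    lr: float = 0.001
    variant: str = "full"
    seed: int = 0
    hidden_dim: int = 256
    latent_dim: int = 256
    alpha: float = 0.1
    beta: float = 0.85
    walk_length: int = 9
    window: int = 3
    walks_per_node: int = 5
    p: float = 1.0
    q: float = 1.0
    negatives_per_pair: int = 5
    negative_distribution: str = "unigram"  # word2vec corpus unigram^0.75, or "uniform"
    rw_lambda: float = 0.001
    rescale_mass_scores: bool = True
    importance_orientation: str = "target"  # orientation fed to the WF fusion
    directed_walks: bool = False
    skipgram_include_mass: bool = True  # regularize [Z | m'] (True) or Z alone
    train_mode: str = "full"  # "full": BCE on all pairs; "sampled": explicit negatives

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    @property
    def use_wf(self) -> bool:
        return self.variant in ("gigae_wf", "full")

    @property
    def use_rwr(self) -> bool:
        return self.variant in ("gigae_rwr", "full")

    @property
    def symmetric_decoder(self) -> bool:
        return self.variant == "gae"


@dataclass
class TrainedModel:
    """Frozen state of the best-validation epoch, sufficient to score any pair."""

    Z: np.ndarray
    m_prime: np.ndarray
    symmetric: bool
    config: TrainConfig
    loss_trace: list[float] = field(default_factory=list)
    val_auroc_trace: list[float] = field(default_factory=list)
    best_epoch: int = -1
    W1: np.ndarray | None = None
    W2: np.ndarray | None = None

    def score_pairs(self, pairs) -> np.ndarray:
        return M.decode_pairs(self.Z, self.m_prime, pairs, symmetric=self.symmetric)

    def save(self, path) -> None:
        np.savez(
            path,
            Z=self.Z,
            m_prime=self.m_prime,
            W1=self.W1 if self.W1 is not None else np.empty(0),
            W2=self.W2 if self.W2 is not None else np.empty(0),
            symmetric=np.array(self.symmetric),
            best_epoch=np.array(self.best_epoch),
            config_json=np.array(json.dumps(asdict(self.config))),
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            config = TrainConfig(**json.loads(str(data["config_json"])))
            return cls(
                Z=data["Z"],
                m_prime=data["m_prime"],
                symmetric=bool(data["symmetric"]),
                config=config,
                best_epoch=int(data["best_epoch"]),
                W1=data["W1"] if data["W1"].size else None,
                W2=data["W2"] if data["W2"].size else None,
            )


@dataclass
class EvalResult:
    auroc: float
    auprc: float
    n_pos: int
    n_neg: int
    per_edge_scores: list[tuple[int, int, float, int]]


def _mass_pipeline(config: TrainConfig, scores_v, m_tilde: np.ndarray):
    """Fused mass m' and d m'/d m~ under the active variant."""
    if config.symmetric_decoder:
        # GAE ablation: masses frozen at a shared constant (0); no gradient.
        return np.zeros_like(m_tilde), 0.0
    if config.use_wf and scores_v is not None:
        return (
            fuse_mass(scores_v, m_tilde, config.alpha, rescale=config.rescale_mass_scores),
            1.0 - config.alpha,
        )
    return m_tilde, 1.0


def train(
    split: EdgeSplit,
    expression: ExpressionMatrix,
    config: TrainConfig,
) -> TrainedModel:
    """Train one variant on a split; returns the best-validation-AUROC checkpoint."""
    train_grn = split.train_grn
    n = train_grn.n_genes
    d = config.latent_dim

    scores = None
    if config.use_wf:
        scores = importance_scores(
            train_grn, beta=config.beta, orientation=config.importance_orientation
        )
        X = fuse_expression(scores, expression, config.alpha)
    else:
        X = expression.values
    A_tilde = M.normalize_adjacency(train_grn)
    adjacency = train_grn.adjacency

    net = M.GravityGAE(
        n_features=X.shape[1],
        hidden_dim=config.hidden_dim,
        latent_dim=d,
        seed=config.seed,
    )
    optimizer = M.Adam(lr=config.lr)

    sg_pairs = sg_negs = None
    if config.use_rwr:
        corpus = W.generate_walks(
            train_grn,
            length=config.walk_length,
            per_node=config.walks_per_node,
            p=config.p,
            q=config.q,
            seed=config.seed + 1,
            directed=config.directed_walks,
        )
        sg_pairs = W.skipgram_pairs(corpus, window=config.window)
        rng = np.random.default_rng(config.seed + 2)
        sg_negs = W.sample_negatives(
            n, len(sg_pairs), config.negatives_per_pair, rng,
            corpus=corpus if config.negative_distribution == "unigram" else None,
        )
        sg_Wpos, sg_Wneg, sg_B = W.pair_count_matrices(sg_pairs, sg_negs, n)

    sampled_pairs = sampled_labels = None
    if config.train_mode == "sampled":
        rng = np.random.default_rng(config.seed + 3)
        pos = np.asarray(split.train_pos)
        from .io import sample_negative_edges

        neg = np.asarray(
            sample_negative_edges(n, train_grn.edges, len(pos), rng)
        )
        sampled_pairs = np.vstack([pos, neg])
        sampled_labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])

    val_pairs = np.asarray(split.val_pos + split.val_neg)
    val_labels = np.concatenate(
        [np.ones(len(split.val_pos)), np.zeros(len(split.val_neg))]
    )

    loss_trace: list[float] = []
    val_trace: list[float] = []
    best = {"auroc": -np.inf, "epoch": -1, "W1": None, "W2": None}

    for epoch in range(config.epochs):
        Z, m_tilde, cache = net.encode(A_tilde, X)
        m_prime, dm_dmtilde = _mass_pipeline(config, scores, m_tilde)

        if config.train_mode == "sampled":
            rec_loss, grad_Z, grad_mp = M.bce_pairs_grads(
                Z, m_prime, sampled_pairs, sampled_labels,
                symmetric=config.symmetric_decoder,
            )
        else:
            rec_loss, grad_Z, grad_mp = M.bce_full_grads(
                Z, m_prime, adjacency, symmetric=config.symmetric_decoder
            )
        total_loss = rec_loss

        if config.use_rwr and len(sg_pairs):
            if config.skipgram_include_mass:
                Z_prime = np.column_stack([Z, m_prime])
            else:
                Z_prime = Z
            sg_loss, sg_grad = W.skipgram_loss_grads_aggregated(
                Z_prime, sg_Wpos, sg_Wneg, sg_B
            )
            total_loss += config.rw_lambda * sg_loss
            grad_Z = grad_Z + config.rw_lambda * sg_grad[:, :d]
            if config.skipgram_include_mass:
                grad_mp = grad_mp + config.rw_lambda * sg_grad[:, d]

        if not np.isfinite(total_loss):
            component = "reconstruction" if not np.isfinite(rec_loss) else "skip-gram"
            raise FloatingPointError(
                f"non-finite {component} loss at epoch {epoch}"
            )
        loss_trace.append(float(total_loss))

        grad_m_tilde = grad_mp * dm_dmtilde
        grad_out = np.column_stack([grad_Z, grad_m_tilde])
        gW1, gW2 = net.backward(A_tilde, cache, grad_out)
        optimizer.step(net.parameters, {"W1": gW1, "W2": gW2})

        # validation AUROC with the updated weights
        Z_v, m_tilde_v, _ = net.encode(A_tilde, X)
        m_prime_v, _ = _mass_pipeline(config, scores, m_tilde_v)
        if len(val_pairs) and len(np.unique(val_labels)) == 2:
            val_scores = M.decode_pairs(
                Z_v, m_prime_v, val_pairs, symmetric=config.symmetric_decoder
            )
            val_auroc = float(roc_auc_score(val_labels, val_scores))
        else:
            val_auroc = float("nan")
        val_trace.append(val_auroc)
        if not np.isnan(val_auroc) and val_auroc > best["auroc"]:
            best = {
                "auroc": val_auroc,
                "epoch": epoch,
                "W1": net.W1.copy(),
                "W2": net.W2.copy(),
            }

    if best["W1"] is not None:
        net.W1, net.W2 = best["W1"], best["W2"]
    Z, m_tilde, _ = net.encode(A_tilde, X)
    m_prime, _ = _mass_pipeline(config, scores, m_tilde)
    return TrainedModel(
        Z=Z,
        m_prime=m_prime,
        symmetric=config.symmetric_decoder,
        config=config,
        loss_trace=loss_trace,
        val_auroc_trace=val_trace,
        best_epoch=int(best["epoch"]),
        W1=net.W1,
        W2=net.W2,
    )


def evaluate(model: TrainedModel, pos_edges, neg_edges) -> EvalResult:
    """AUROC (midrank ties) and AUPRC (step integration) on labeled edge sets."""
    pos_edges, neg_edges = list(pos_edges), list(neg_edges)
    if not pos_edges or not neg_edges:
        raise ValueError("both positive and negative edge sets must be non-empty")
    pairs = np.asarray(pos_edges + neg_edges)
    labels = np.concatenate([np.ones(len(pos_edges)), np.zeros(len(neg_edges))])
    scores = model.score_pairs(pairs)
    per_edge = [
        (int(i), int(j), float(s), int(y))
        for (i, j), s, y in zip(pairs, scores, labels)
    ]
    return EvalResult(
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
        n_pos=len(pos_edges),
        n_neg=len(neg_edges),
        per_edge_scores=per_edge,
    )


def rank_novel_edges(
    model: TrainedModel,
    grn: DirectedGRN,
    sources=None,
    top_k: int = 20,
) -> list[tuple[int, int, float]]:
    """Top-k unknown directed pairs by decoder score.

    Candidates are all ordered pairs (i, j), i != j, absent from ``grn``;
    ``sources`` optionally restricts i (e.g. to a TF of interest). Ties break
    by (i, j) lexicographic order.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    n = grn.n_genes
    src = np.arange(n) if sources is None else np.asarray(sorted(sources))
    known = grn.edges
    candidates = [
        (int(i), int(j)) for i in src for j in range(n) if i != j and (i, j) not in known
    ]
    if not candidates:
        return []
    scores = model.score_pairs(np.asarray(candidates))
    order = sorted(range(len(candidates)), key=lambda k: (-scores[k], candidates[k]))
    return [
        (candidates[k][0], candidates[k][1], float(scores[k]))
        for k in order[:top_k]
    ]


def run_ablation(
    grn: DirectedGRN,
    expression: ExpressionMatrix,
    seeds=(0, 1, 2, 3, 4),
    variants=VARIANTS,
    base_config: TrainConfig | None = None,
    fractions=(0.85, 0.05, 0.10),
):
    """Split + train + test-evaluate every variant over several seeds.

    Returns a list of dict records (variant, seed, auroc, auprc) — one
    train/val/test split per seed, shared across variants for a paired
    comparison.
    """
    from .io import split_edges

    base = base_config or TrainConfig()
    records = []
    for seed in seeds:
        split = split_edges(grn, fractions=fractions, seed=seed)
        for variant in variants:
            cfg = TrainConfig(**{**asdict(base), "variant": variant, "seed": seed})
            trained = train(split, expression, cfg)
            res = evaluate(trained, split.test_pos, split.test_neg)
            records.append(
                {"variant": variant, "seed": seed, "auroc": res.auroc, "auprc": res.auprc}
            )
    return records


def run_record(config: TrainConfig, metrics: dict, path=None) -> dict:
    """JSON-serializable record of a run (config, seed, metrics, package version)."""
    from . import __version__

    record = {"config": asdict(config), "seed": config.seed,
              "metrics": metrics, "version": __version__}
    if path is not None:
        Path(path).write_text(json.dumps(record, indent=2))
    return record
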