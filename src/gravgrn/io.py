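"""Reading gene networks and expression matrices, and building supervised edge splits.

Conventions used throughout the package:

* gene indices are 0-based positions in a :class:`GeneVocabulary`;
* a directed edge ``(i, j)`` always means *gene i regulates gene j*, so the
  adjacency matrix satisfies ``A[i, j] == 1`` iff ``i -> j`` is a known edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp


class GraphIOError(ValueError):
    """Raised for malformed network or expression inputs."""


@dataclass(frozen=True)
class GeneVocabulary:
    """Ordered, unique gene identifiers with a bijective name -> index map."""

    names: tuple[str, ...]
    index: dict[str, int] = field(compare=False)

    @classmethod
    def from_names(cls, names) -> "GeneVocabulary":
        names = tuple(str(n) for n in names)
        index = {}
        for i, name in enumerate(names):
            if name in index:
                raise GraphIOError(f"duplicate gene identifier: {name!r}")
            index[name] = i
        return cls(names=names, index=index)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.index


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of non-negative expression values."""

    values: np.ndarray
    gene_axis: GeneVocabulary

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GraphIOError("expression matrix must be 2-dimensional")
        if self.values.shape[0] != len(self.gene_axis):
            raise GraphIOError(
                f"row count {self.values.shape[0]} does not match vocabulary size "
                f"{len(self.gene_axis)}"
            )
        if np.isnan(self.values).any():
            raise GraphIOError("expression matrix contains missing values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def cell_count(self) -> int:
        return self.values.shape[1]


@dataclass
class DirectedGRN:
    """A directed gene regulatory network as a set of (regulator, target) index pairs."""

    edges: frozenset[tuple[int, int]]
    n_genes: int

    def __post_init__(self):
        self.edges = frozenset((int(i), int(j)) for i, j in self.edges)
        for i, j in self.edges:
            if not (0 <= i < self.n_genes and 0 <= j < self.n_genes):
                raise GraphIOError(f"edge ({i},{j}) outside 0..{self.n_genes - 1}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Sparse 0/1 adjacency with A[i, j] = 1 iff i regulates j."""
        if not self.edges:
            return sp.csr_matrix((self.n_genes, self.n_genes))
        rows, cols = zip(*sorted(self.edges))
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n_genes, self.n_genes))

    def out_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_genes, dtype=int)
        for i, _ in self.edges:
            deg[i] += 1
        return deg

    def in_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_genes, dtype=int)
        for _, j in self.edges:
            deg[j] += 1
        return deg

    def sorted_edges(self) -> list[tuple[int, int]]:
        return sorted(self.edges)

    def reverse(self) -> "DirectedGRN":
        """The edge-reversed network (targets become sources)."""
        return DirectedGRN(
            edges=frozenset((j, i) for i, j in self.edges), n_genes=self.n_genes
        )


@dataclass
class EdgeSplit:
    """Train/validation/test partition of known edges with sampled negatives."""

    train_pos: list[tuple[int, int]]
    val_pos: list[tuple[int, int]]
    test_pos: list[tuple[int, int]]
    val_neg: list[tuple[int, int]]
    test_neg: list[tuple[int, int]]
    n_genes: int

    @property
    def train_grn(self) -> DirectedGRN:
        """Network containing only the training positives (the model's prior)."""
        return DirectedGRN(edges=frozenset(self.train_pos), n_genes=self.n_genes)

    @property
    def train_adjacency(self) -> sp.csr_matrix:
        return self.train_grn.adjacency


def load_expression(path, delimiter: str = ",") -> ExpressionMatrix:
    """Load a genes x cells matrix from delimited text.

    First column holds gene identifiers; the header row holds cell identifiers.
    Duplicated gene identifiers and non-numeric or missing cells are errors.
    """
    path = Path(path)
    if not path.exists():
        raise GraphIOError(f"no such file: {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise GraphIOError(f"duplicate gene identifiers in {path.name}: {dupes}")
    try:
        values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        # locate the offending cell for a useful message
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy().argmax()]
                raise GraphIOError(
                    f"non-numeric value in {path.name} at gene {gene!r}, cell {col!r}"
                ) from exc
        raise GraphIOError(f"non-numeric value in {path.name}") from exc
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise GraphIOError(
            f"missing value in {path.name} at gene {df.index[r]!r}, cell {df.columns[c]!r}"
        )
    vocab = GeneVocabulary.from_names(df.index)
    return ExpressionMatrix(values=values, gene_axis=vocab)


def load_edge_list(
    path,
    vocab: GeneVocabulary,
    delimiter: str | None = None,
    unknown_policy: str = "error",
) -> DirectedGRN:
    """Load a two-column (regulator, target) edge list mapped onto ``vocab``.

    A header row is autodetected: if neither token of the first row is a known
    gene name, the row is treated as a header. Duplicate edges collapse to one
    with a warning. ``unknown_policy`` is ``"error"`` (default) or ``"drop"``.
    """
    if unknown_policy not in ("error", "drop"):
        raise GraphIOError(f"unknown_policy must be 'error' or 'drop', got {unknown_policy!r}")
    path = Path(path)
    if not path.exists():
        raise GraphIOError(f"no such file: {path}")
    if path.stat().st_size == 0:
        return DirectedGRN(edges=frozenset(), n_genes=len(vocab))
    try:
        df = pd.read_csv(path, sep=delimiter, header=None, dtype=str, engine="python")
    except pd.errors.EmptyDataError:
        return DirectedGRN(edges=frozenset(), n_genes=len(vocab))
    if df.empty:
        return DirectedGRN(edges=frozenset(), n_genes=len(vocab))
    if df.shape[1] < 2:
        raise GraphIOError(f"{path.name}: expected two columns (regulator, target)")
    df = df.iloc[:, :2]
    first = df.iloc[0]
    if first.iloc[0] not in vocab and first.iloc[1] not in vocab:
        df = df.iloc[1:]  # header row
    edges: set[tuple[int, int]] = set()
    n_dupes = 0
    for _, (src, dst) in df.iterrows():
        src, dst = str(src).strip(), str(dst).strip()
        if src not in vocab or dst not in vocab:
            if unknown_policy == "error":
                missing = src if src not in vocab else dst
                raise GraphIOError(f"{path.name}: gene {missing!r} not in vocabulary")
            warnings.warn(f"dropping edge with unknown gene: ({src}, {dst})")
            continue
        edge = (vocab.index[src], vocab.index[dst])
        if edge in edges:
            n_dupes += 1
        edges.add(edge)
    if n_dupes:
        warnings.warn(f"{path.name}: collapsed {n_dupes} duplicate edge(s)")
    return DirectedGRN(edges=frozenset(edges), n_genes=len(vocab))


def sample_negative_edges(
    n_genes: int,
    known_edges: frozenset[tuple[int, int]],
    n_needed: int,
    rng: np.random.Generator,
    exclude: set[tuple[int, int]] | None = None,
    sources: np.ndarray | None = None,
    max_draw_factor: int = 1000,
) -> list[tuple[int, int]]:
    """Sample ordered pairs (u, v), u != v, absent from the known edge set.

    ``sources`` optionally restricts u to a subset of genes (e.g. prior TFs).
    Rejection sampling with a cap of ``max_draw_factor * n_needed`` draws.
    """
    if n_needed == 0:
        return []
    forbidden = set(known_edges)
    if exclude:
        forbidden |= set(exclude)
    src_pool = np.arange(n_genes) if sources is None else np.asarray(sources)
    negatives: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    draws = 0
    cap = max_draw_factor * n_needed
    while len(negatives) < n_needed:
        if draws >= cap:
            raise GraphIOError(
                f"could not sample {n_needed} negatives in {cap} draws; "
                "graph too dense or source pool too small"
            )
        batch = min(n_needed * 4, cap - draws)
        us = src_pool[rng.integers(0, len(src_pool), size=batch)]
        vs = rng.integers(0, n_genes, size=batch)
        draws += batch
        for u, v in zip(us.tolist(), vs.tolist()):
            if u == v:
                continue
            pair = (u, v)
            if pair in forbidden or pair in seen:
                continue
            seen.add(pair)
            negatives.append(pair)
            if len(negatives) == n_needed:
                break
    return negatives


def split_edges(
    grn: DirectedGRN,
    fractions: tuple[float, float, float] = (0.85, 0.05, 0.10),
    seed: int = 0,
    tf_sources_only: bool = False,
) -> EdgeSplit:
    """Partition known edges into train/val/test positives and sample balanced negatives.

    Sizes are train = floor(f_train * E), val = floor(f_val * E), test = remainder,
    so the partition is exact. Negatives are matched 1:1 to val/test positives and
    are verifiably absent from the full known edge set. With ``tf_sources_only``
    the negative sources are restricted to genes with out-degree > 0 in the prior.
    """
    f_train, f_val, f_test = fractions
    if min(fractions) < 0 or abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise GraphIOError(f"fractions must be non-negative and sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    edges = grn.sorted_edges()
    n = len(edges)
    order = rng.permutation(n)
    n_train = int(np.floor(f_train * n))
    n_val = int(np.floor(f_val * n))
    train_pos = [edges[k] for k in order[:n_train]]
    val_pos = [edges[k] for k in order[n_train : n_train + n_val]]
    test_pos = [edges[k] for k in order[n_train + n_val :]]

    sources = None
    if tf_sources_only:
        sources = np.flatnonzero(grn.out_degrees() > 0)
    val_neg = sample_negative_edges(
        grn.n_genes, grn.edges, len(val_pos), rng, sources=sources
    )
    test_neg = sample_negative_edges(
        grn.n_genes, grn.edges, len(test_pos), rng, exclude=set(val_neg), sources=sources
    )
    return EdgeSplit(
        train_pos=train_pos,
        val_pos=val_pos,
        test_pos=test_pos,
        val_neg=val_neg,
        test_neg=test_neg,
        n_genes=grn.n_genes,
    )


_SPLIT_FILES = ("train_pos", "val_pos", "val_neg", "test_pos", "test_neg")


def save_split(split: EdgeSplit, directory, vocab: GeneVocabulary | None = None) -> None:
    """Write a split to a directory of two-column TSV edge lists for exact rerun."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _SPLIT_FILES:
        edges = getattr(split, name)
        with open(directory / f"{name}.tsv", "w") as fh:
            for i, j in edges:
                if vocab is not None:
                    fh.write(f"{vocab.names[i]}\t{vocab.names[j]}\n")
                else:
                    fh.write(f"{i}\t{j}\n")


def load_split(directory, n_genes: int, vocab: GeneVocabulary | None = None) -> EdgeSplit:
    directory = Path(directory)
    parts = {}
    for name in _SPLIT_FILES:
        edges = []
        fp = directory / f"{name}.tsv"
        with open(fp) as fh:
            for line in fh:
                a, b = line.rstrip("\n").split("\t")
                if vocab is not None:
                    edges.append((vocab.index[a], vocab.index[b]))
                else:
                    edges.append((int(a), int(b)))
        parts[name] = edges
    return EdgeSplit(n_genes=n_genes, **parts)
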