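"""Phenotype-profile embeddings via random walks and skip-gram.

An annotation graph is built over phenotype classes and entities (diseases
or genes): subclass edges from the phenotype ontology plus one annotation
edge per (entity, phenotype) link.  Node neighbourhoods are sampled with
uniform random walks, and the resulting walk corpus is fed to a skip-gram
model with negative sampling (word2vec SGNS) to place every node in a
common vector space.  Entity-entity similarity is the cosine of their
vectors; ranking quality is summarised as ROC AUC.

Defaults mirror common ontology-embedding practice: vector size 100, window
5, minimum occurrence count 1, skip-gram, walk depth 3.  Training is
single-threaded and fully seeded, so a (graph, seed) pair reproduces the
same vectors bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .errors import EmptyCorpusError, UndefinedAUCError, UnknownClassError, ZeroNormError
from .ontology import OntologyGraph

__all__ = [
    "EntityProfile",
    "EmbeddingSpace",
    "build_annotation_graph",
    "random_walk_corpus",
    "train_embeddings",
    "embed_profiles",
    "cosine",
    "roc_auc",
]


@dataclass(frozen=True)
class EntityProfile:
    """An entity (disease or gene) with its set of annotated phenotype classes."""

    entity_id: str
    entity_kind: str  # disease | gene
    phenotypes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.phenotypes:
            raise ValueError(f"entity {self.entity_id!r} has an empty phenotype profile")


@dataclass
class EmbeddingSpace:
    """Trained node vectors plus the hyperparameters that produced them."""

    vectors: dict[str, np.ndarray]
    dim: int
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, node_id: str) -> np.ndarray:
        return self.vectors[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.vectors

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for node in sorted(self.vectors):
                vals = "\t".join(f"{x:.8g}" for x in self.vectors[node])
                fh.write(f"{node}\t{vals}\n")


def build_annotation_graph(
    g_pheno: OntologyGraph, profiles: Iterable[EntityProfile]
) -> nx.Graph:
    """Undirected walkable graph: phenotype subclass edges + annotation edges.

    Every phenotype class of the ontology becomes a node; every entity
    becomes a node linked to each phenotype in its profile.  Edges carry an
    ``etype`` attribute (subclass / annotation).
    """
    g = nx.Graph()
    g.add_nodes_from(g_pheno.classes)
    for child, parent in g_pheno.subclass_edges:
        g.add_edge(child, parent, etype="subclass")
    for profile in profiles:
        for phen in profile.phenotypes:
            if phen not in g_pheno:
                raise UnknownClassError(
                    f"profile {profile.entity_id!r} annotates unknown class {phen!r}"
                )
            g.add_edge(profile.entity_id, phen, etype="annotation")
    return g


def random_walk_corpus(
    g: nx.Graph,
    walk_depth: int = 3,
    walks_per_node: int = 10,
    seed: int = 0,
) -> list[list[str]]:
    """Uniform random walks from every node; fully reproducible from the seed.

    Each walk takes up to ``walk_depth`` uniform neighbour steps (sequence
    length <= walk_depth + 1); an isolated node yields single-node walks.
    """
    if walk_depth < 1:
        raise ValueError("walk_depth must be >= 1")
    rng = np.random.default_rng(seed)
    neighbors = {n: sorted(g.neighbors(n)) for n in g.nodes}
    walks: list[list[str]] = []
    for start in sorted(g.nodes):
        for _ in range(walks_per_node):
            walk = [start]
            for _ in range(walk_depth):
                nbrs = neighbors[walk[-1]]
                if not nbrs:
                    break
                walk.append(nbrs[rng.integers(len(nbrs))])
            walks.append(walk)
    return walks


def train_embeddings(
    walks: Sequence[Sequence[str]],
    dim: int = 100,
    window: int = 5,
    min_count: int = 1,
    seed: int = 0,
    epochs: int = 5,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
) -> EmbeddingSpace:
    """Skip-gram with negative sampling over a walk corpus.

    Plain SGNS: for every (center, context) pair within ``window`` of each
    other, the center's input vector is pulled toward the context's output
    vector and pushed from ``negative`` nodes drawn from the unigram^0.75
    distribution; the learning rate decays linearly from ``alpha`` to
    ``min_alpha``.  Nodes occurring fewer than ``min_count`` times are
    dropped from the vocabulary.  Deterministic for a fixed seed.
    """
    walks = [list(w) for w in walks if w]
    if not walks:
        raise EmptyCorpusError("cannot train embeddings on an empty walk corpus")

    freq: dict[str, int] = {}
    for walk in walks:
        for node in walk:
            freq[node] = freq.get(node, 0) + 1
    vocab = sorted(n for n, c in freq.items() if c >= min_count)
    if not vocab:
        raise EmptyCorpusError(f"no node reaches min_count={min_count}")
    index = {n: i for i, n in enumerate(vocab)}

    rng = np.random.default_rng(seed)
    n_vocab = len(vocab)
    w_in = (rng.random((n_vocab, dim)) - 0.5) / dim
    w_out = np.zeros((n_vocab, dim))

    # unigram^0.75 negative-sampling distribution
    counts = np.array([freq[n] for n in vocab], dtype=float) ** 0.75
    noise_p = counts / counts.sum()

    # materialise the (center, context) pair list once; corpora here are small
    pairs: list[tuple[int, int]] = []
    for walk in walks:
        ids = [index[n] for n in walk if n in index]
        for i, center in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((center, ids[j]))
    if not pairs:
        # single-node walks only: vectors stay at initialisation
        vectors = {n: w_in[index[n]].copy() for n in vocab}
        return EmbeddingSpace(vectors, dim, {"window": window, "min_count": min_count, "seed": seed})

    pair_arr = np.array(pairs, dtype=np.int64)
    total_steps = epochs * len(pair_arr)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(pair_arr))
        negs = rng.choice(n_vocab, size=(len(pair_arr), negative), p=noise_p)
        for k in order:
            center, context = pair_arr[k]
            lr = max(min_alpha, alpha * (1.0 - step / total_steps))
            step += 1
            targets = np.concatenate(([context], negs[k]))
            labels = np.zeros(len(targets))
            labels[0] = 1.0
            v = w_in[center]
            u = w_out[targets]
            scores = 1.0 / (1.0 + np.exp(-np.clip(u @ v, -30, 30)))
            g = (labels - scores) * lr
            w_in[center] = v + g @ u
            w_out[targets] += np.outer(g, v)

    vectors = {n: w_in[index[n]].copy() for n in vocab}
    meta = {
        "dim": dim,
        "window": window,
        "min_count": min_count,
        "seed": seed,
        "epochs": epochs,
        "negative": negative,
    }
    return EmbeddingSpace(vectors, dim, meta)


def embed_profiles(
    g_pheno: OntologyGraph,
    profiles: Iterable[EntityProfile],
    dim: int = 100,
    window: int = 5,
    min_count: int = 1,
    walk_depth: int = 3,
    walks_per_node: int = 10,
    seed: int = 0,
    epochs: int = 5,
) -> EmbeddingSpace:
    """Convenience pipeline: annotation graph -> walks -> skip-gram vectors."""
    graph = build_annotation_graph(g_pheno, profiles)
    walks = random_walk_corpus(graph, walk_depth=walk_depth, walks_per_node=walks_per_node, seed=seed)
    return train_embeddings(
        walks, dim=dim, window=window, min_count=min_count, seed=seed, epochs=epochs
    )


def cosine(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine similarity v1.v2 / (|v1| |v2|), in [-1, 1]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError(f"dimension mismatch: {v1.shape} vs {v2.shape}")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ZeroNormError("cosine similarity of a zero vector is undefined")
    return float(np.dot(v1, v2) / (n1 * n2))


def roc_auc(scores: Iterable[tuple[float, str | int]]) -> float:
    """ROC AUC via the rank (Mann-Whitney U) formulation; ties count 1/2.

    Labels may be "pos"/"neg" or truthy/falsy ints.
    """
    values, labels = [], []
    for value, label in scores:
        values.append(float(value))
        labels.append(1 if label in ("pos", 1, True) else 0)
    y = np.array(labels)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC needs at least one positive and one negative")
    ranks = rankdata(values)  # average ranks handle ties as 1/2
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
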