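"""Network embedding: biased random walks + skip-gram with negative sampling.

Every gene of the high-confidence network is mapped to a fixed-length real
vector by (1) sampling a corpus of second-order random walks (the node2vec
scheme: return parameter ``p`` and in-out parameter ``q`` bias each step
towards or away from the previous node) and (2) training skip-gram with
negative sampling (SGNS) on the walk corpus, treating walks as sentences and
genes as words.

The trainer is a self-contained, vectorised numpy implementation of SGNS
(mini-batch SGD, unigram^0.75 negative-sampling distribution, linearly
decaying learning rate, dynamic window).  It is single-threaded and driven by
one seeded generator, so training is bit-for-bit reproducible — the property
the downstream association scores rely on.

Defaults: 10 walks per node of length 30, window 10, 64 dimensions,
min_count 1 (every walked gene receives a vector), p = q = 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidParameterError
from .netio import WeightedNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkParams:
    num_walks: int = 10
    walk_length: int = 30
    p: float = 1.0
    q: float = 1.0
    weighted: bool = False
    seed: int = 0


@dataclass
class WalkCorpus:
    """A corpus of random walks; each walk is a sequence of gene symbols."""

    walks: list[list[str]]
    params: WalkParams

    def __len__(self) -> int:
        return len(self.walks)


@dataclass(frozen=True)
class TrainParams:
    dim: int = 64
    window: int = 10
    min_count: int = 1
    epochs: int = 5
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    batch_words: int = 6  # recorded for provenance; no numerical consequence
    seed: int = 0


@dataclass
class EmbeddedNetwork:
    """Gene -> fixed-length feature vector, with the training manifest."""

    genes: tuple[str, ...]
    matrix: np.ndarray  # (n_genes, dim), float64
    params: dict = field(default_factory=dict)
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.matrix.shape[0] != len(self.genes):
            raise InvalidParameterError("matrix rows must match gene list")
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidParameterError("embedding contains non-finite entries")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def vector(self, gene: str) -> np.ndarray:
        try:
            return self.matrix[self._index[gene]]
        except KeyError:
            raise LookupError(f"gene {gene!r} is not embedded") from None

    def rows(self, genes: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._index[g] for g in genes]
        except KeyError as exc:
            raise LookupError(f"gene {exc.args[0]!r} is not embedded") from None
        return self.matrix[idx]

    # -- persistence (TSV matrix + JSON manifest) ---------------------------

    def save(self, prefix) -> None:
        prefix = Path(prefix)
        with open(f"{prefix}.tsv", "w") as fh:
            for g, row in zip(self.genes, self.matrix):
                fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        with open(f"{prefix}.manifest.json", "w") as fh:
            json.dump({"dim": self.dim, "n_genes": len(self.genes), **self.params}, fh, indent=2)

    @classmethod
    def load(cls, prefix) -> "EmbeddedNetwork":
        prefix = Path(prefix)
        genes, rows = [], []
        with open(f"{prefix}.tsv") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                genes.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        manifest_path = Path(f"{prefix}.manifest.json")
        params = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
        return cls(genes=tuple(genes), matrix=np.asarray(rows, dtype=np.float64), params=params)


# ---------------------------------------------------------------------------
# walks
# ---------------------------------------------------------------------------


def generate_walks(
    net: WeightedNetwork,
    num_walks: int = 10,
    walk_length: int = 30,
    p: float = 1.0,
    q: float = 1.0,
    weighted: bool = False,
    seed: int = 0,
) -> WalkCorpus:
    """Sample ``num_walks`` second-order random walks of ``walk_length`` nodes
    from every gene of the network.

    With p = q = 1 the walk is the ordinary first-order random walk.  Dead
    ends truncate the walk (an isolated node yields the length-1 walk of
    itself).  Transitions are uniform over neighbors unless ``weighted``,
    in which case edge confidences weight the choice.
    """
    if net.n_genes == 0:
        raise InvalidParameterError("empty network: no genes to walk from")
    if p <= 0 or q <= 0:
        raise InvalidParameterError("p and q must be positive")
    rng = np.random.default_rng(seed)
    genes = list(net.genes)
    index = {g: i for i, g in enumerate(genes)}
    nbrs: list[np.ndarray] = [None] * len(genes)  # type: ignore[list-item]
    wts: list[np.ndarray] = [None] * len(genes)  # type: ignore[list-item]
    adj_lists: list[list[tuple[int, float]]] = [[] for _ in genes]
    for a, b, c in net.edges:
        ia, ib = index[a], index[b]
        adj_lists[ia].append((ib, float(c)))
        adj_lists[ib].append((ia, float(c)))
    nbr_sets: list[set[int]] = []
    for i, lst in enumerate(adj_lists):
        lst.sort()
        nbrs[i] = np.array([j for j, _ in lst], dtype=np.int64)
        w = np.array([w for _, w in lst], dtype=np.float64)
        wts[i] = w / w.sum() if len(w) and weighted else w
        nbr_sets.append({j for j, _ in lst})

    second_order = not (p == 1.0 and q == 1.0)
    walks: list[list[str]] = []
    for _ in range(num_walks):
        for start in range(len(genes)):
            walk = [start]
            prev = -1
            while len(walk) < walk_length:
                cur = walk[-1]
                cand = nbrs[cur]
                if len(cand) == 0:
                    break  # dead end: truncate
                if not second_order or prev < 0:
                    if weighted:
                        nxt = int(cand[_choice(rng, wts[cur])])
                    else:
                        nxt = int(cand[rng.integers(len(cand))])
                else:
                    bias = np.ones(len(cand))
                    prev_nbrs = nbr_sets[prev]
                    for k, j in enumerate(cand):
                        if j == prev:
                            bias[k] = 1.0 / p
                        elif j not in prev_nbrs:
                            bias[k] = 1.0 / q
                    if weighted:
                        bias *= wts[cur]
                    bias /= bias.sum()
                    nxt = int(cand[_choice(rng, bias)])
                prev = cur
                walk.append(nxt)
            walks.append([genes[i] for i in walk])
    params = WalkParams(num_walks, walk_length, p, q, weighted, seed)
    return WalkCorpus(walks=walks, params=params)


def _choice(rng: np.random.Generator, probs: np.ndarray) -> int:
    return int(np.searchsorted(np.cumsum(probs), rng.random(), side="right"))


# ---------------------------------------------------------------------------
# skip-gram with negative sampling
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _build_pairs(
    sentences: list[np.ndarray], window: int, rng: np.random.Generator
) -> np.ndarray:
    """(center, context) index pairs with a per-center dynamic window drawn
    uniformly from 1..window, as in word2vec."""
    chunks = []
    for sent in sentences:
        n = len(sent)
        if n < 2:
            continue
        b = rng.integers(1, window + 1, size=n)
        for i in range(n):
            lo, hi = max(0, i - b[i]), min(n, i + b[i] + 1)
            ctx = np.concatenate([sent[lo:i], sent[i + 1 : hi]])
            if len(ctx):
                chunks.append(np.column_stack([np.full(len(ctx), sent[i]), ctx]))
    if not chunks:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(chunks).astype(np.int64)


def train_embedding(
    corpus: WalkCorpus,
    dim: int = 64,
    window: int = 10,
    min_count: int = 1,
    epochs: int = 5,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    seed: int = 0,
    batch_size: int = 1024,
) -> EmbeddedNetwork:
    """Train SGNS over the walk corpus and return the input-side vectors."""
    if dim < 1:
        raise InvalidParameterError(f"dim must be >= 1, got {dim}")
    if window < 1:
        raise InvalidParameterError(f"window must be >= 1, got {window}")
    if not corpus.walks:
        raise InvalidParameterError("empty walk corpus")

    counts: dict[str, int] = {}
    for walk in corpus.walks:
        for g in walk:
            counts[g] = counts.get(g, 0) + 1
    vocab = sorted(g for g, c in counts.items() if c >= min_count)
    if not vocab:
        raise InvalidParameterError("no gene meets min_count")
    index = {g: i for i, g in enumerate(vocab)}
    sentences = [
        np.array([index[g] for g in walk if g in index], dtype=np.int64)
        for walk in corpus.walks
    ]

    v = len(vocab)
    freq = np.array([counts[g] for g in vocab], dtype=np.float64)
    noise = freq**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(seed)
    w_in = (rng.random((v, dim)) - 0.5) / dim
    w_out = np.zeros((v, dim))

    # expected total pair count for the learning-rate schedule
    approx_pairs = sum(len(s) for s in sentences) * (window + 1) / 2 * 2
    total = max(1.0, approx_pairs * epochs)
    done = 0.0
    k = negative
    # mini-batch updates accumulate ~batch*(1+k)/v gradient contributions per
    # row at stale parameters; cap the batch so that stays a contraction
    batch_size = max(16, min(batch_size, int(0.5 * v / (max(1, k) * alpha))))
    for _ in range(epochs):
        pairs = _build_pairs(sentences, window, rng)
        rng.shuffle(pairs, axis=0)
        for off in range(0, len(pairs), batch_size):
            batch = pairs[off : off + batch_size]
            c, o = batch[:, 0], batch[:, 1]
            lr = max(min_alpha, alpha * (1.0 - done / total))
            wc = w_in[c]  # (B, d)
            co = w_out[o]  # (B, d)
            g_pos = (_sigmoid(np.einsum("bd,bd->b", wc, co)) - 1.0) * lr  # (B,)
            if k > 0:
                neg = np.searchsorted(noise_cdf, rng.random((len(c), k)))
                cn = w_out[neg]  # (B, k, d)
                g_neg = _sigmoid(np.einsum("bd,bkd->bk", wc, cn)) * lr  # (B, k)
                grad_c = g_pos[:, None] * co + np.einsum("bk,bkd->bd", g_neg, cn)
                np.subtract.at(
                    w_out,
                    neg.ravel(),
                    (g_neg[:, :, None] * wc[:, None, :]).reshape(-1, dim),
                )
            else:
                grad_c = g_pos[:, None] * co
            np.subtract.at(w_out, o, g_pos[:, None] * wc)
            np.subtract.at(w_in, c, grad_c)
            done += len(batch)

    params = {
        **asdict(corpus.params),
        **asdict(
            TrainParams(
                dim=dim,
                window=window,
                min_count=min_count,
                epochs=epochs,
                negative=negative,
                alpha=alpha,
                min_alpha=min_alpha,
                seed=seed,
            )
        ),
    }
    return EmbeddedNetwork(genes=tuple(vocab), matrix=w_in, params=params)


def embed_network(
    net_high: WeightedNetwork,
    walk_params: WalkParams | None = None,
    train_params: TrainParams | None = None,
) -> EmbeddedNetwork:
    """Walks + SGNS in one call; the returned embedding carries the full
    parameter manifest."""
    if net_high.n_genes == 0:
        raise InvalidParameterError("empty universe")
    wp = walk_params or WalkParams()
    tp = train_params or TrainParams(seed=wp.seed)
    corpus = generate_walks(
        net_high,
        num_walks=wp.num_walks,
        walk_length=wp.walk_length,
        p=wp.p,
        q=wp.q,
        weighted=wp.weighted,
        seed=wp.seed,
    )
    logger.info(
        "embedding %d genes, %d edges, %d walks",
        net_high.n_genes,
        net_high.n_edges,
        len(corpus),
    )
    return train_embedding(
        corpus,
        dim=tp.dim,
        window=tp.window,
        min_count=tp.min_count,
        epochs=tp.epochs,
        negative=tp.negative,
        alpha=tp.alpha,
        min_alpha=tp.min_alpha,
        seed=tp.seed,
    )
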