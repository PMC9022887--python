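"""Association Scores: cosine similarity between gene embedding vectors.

The Association Score of a gene pair is the cosine of the angle between the
two genes' learned feature vectors; it serves as a predicted strength of
functional association.  Over n genes there are C(n, 2) pairwise scores; they
are always evaluated on demand or blockwise, never materialised as the full
dense n x n matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .embedding import EmbeddedNetwork
from .errors import InvalidParameterError

#: default score-bin edges for the confidence-agreement summary
DEFAULT_SCORE_BINS = (-1.0, 0.4, 0.6, 0.8, 1.0)


def all_pair_count(universe_size: int) -> int:
    """Number of unordered gene pairs, C(n, 2)."""
    if universe_size < 2:
        raise InvalidParameterError(f"need >= 2 genes, got {universe_size}")
    return math.comb(universe_size, 2)


def _unit_rows(m: np.ndarray, what: str = "gene") -> np.ndarray:
    norms = np.linalg.norm(m, axis=1)
    if np.any(norms == 0):
        raise InvalidParameterError(f"zero embedding vector: cosine undefined for a {what}")
    return m / norms[:, None]


def association_score(emb: EmbeddedNetwork, a: str, b: str) -> float:
    """Cosine similarity between the embedding vectors of genes ``a``, ``b``."""
    va, vb = emb.vector(a), emb.vector(b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise InvalidParameterError(f"zero vector for {a if na == 0 else b!r}")
    return float(np.dot(va, vb) / (na * nb))


def score_many(
    emb: EmbeddedNetwork,
    pairs: Sequence[tuple[str, str]],
    block_size: int = 65536,
) -> np.ndarray:
    """Association Scores for an explicit pair list, evaluated blockwise.

    Peak working set is bounded by ``block_size`` pairs; results equal the
    per-pair :func:`association_score` elementwise.
    """
    pairs = list(pairs)
    out = np.empty(len(pairs), dtype=np.float64)
    for off in range(0, len(pairs), block_size):
        chunk = pairs[off : off + block_size]
        a = _unit_rows(emb.rows([p[0] for p in chunk]))
        b = _unit_rows(emb.rows([p[1] for p in chunk]))
        out[off : off + len(chunk)] = np.einsum("ij,ij->i", a, b)
    return out


def block_scores(
    emb: EmbeddedNetwork, genes_a: Sequence[str], genes_b: Sequence[str]
) -> np.ndarray:
    """Dense |A| x |B| block of Association Scores between two gene lists."""
    a = _unit_rows(emb.rows(genes_a))
    b = _unit_rows(emb.rows(genes_b))
    return np.clip(a @ b.T, -1.0, 1.0)


@dataclass
class ConfidenceAgreementTable:
    """Per-score-bin summary of known edge confidences.

    One row per score bin (lo, hi]: pair count, confidence mean and
    quartiles, and the fraction of pairs at or above the confidence
    threshold.  Empty bins carry NaN summaries (absent, not zero).
    """

    table: pd.DataFrame
    conf_threshold: int

    def __repr__(self) -> str:  # pragma: no cover
        return f"ConfidenceAgreementTable(threshold={self.conf_threshold})\n{self.table}"


def confidence_agreement(
    scores: np.ndarray,
    confidences: np.ndarray,
    score_bin_edges: Sequence[float] = DEFAULT_SCORE_BINS,
    conf_threshold: int = 800,
) -> ConfidenceAgreementTable:
    """Summarise how known confidences track predicted Association Scores.

    ``scores`` and ``confidences`` are aligned over the same pair list.  Bins
    are half-open (lo, hi], except the first which includes its lower edge.
    """
    scores = np.asarray(scores, dtype=float)
    confidences = np.asarray(confidences, dtype=float)
    if scores.shape != confidences.shape:
        raise InvalidParameterError("scores and confidences must be aligned")
    edges = list(score_bin_edges)
    if sorted(edges) != edges or len(edges) < 2:
        raise InvalidParameterError("score_bin_edges must be increasing")
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == edges[0]:
            mask = (scores >= lo) & (scores <= hi)
        else:
            mask = (scores > lo) & (scores <= hi)
        conf = confidences[mask]
        if conf.size == 0:
            rows.append((lo, hi, 0, *([np.nan] * 5)))
            continue
        q1, q2, q3 = np.percentile(conf, [25, 50, 75])
        rows.append(
            (lo, hi, conf.size, conf.mean(), q1, q2, q3, float(np.mean(conf >= conf_threshold)))
        )
    table = pd.DataFrame(
        rows,
        columns=["score_lo", "score_hi", "n_pairs", "conf_mean", "conf_q1", "conf_median", "conf_q3", "frac_ge_threshold"],
    )
    return ConfidenceAgreementTable(table=table, conf_threshold=conf_threshold)


def iter_scored_edges(
    emb: EmbeddedNetwork, edges: Iterable[tuple[str, str, int]], block_size: int = 65536
):
    """Yield (gene_a, gene_b, confidence, score) for network edges whose
    endpoints are embedded; used to reproduce the agreement analysis."""
    buf: list[tuple[str, str, int]] = []

    def flush():
        scores = score_many(emb, [(a, b) for a, b, _ in buf], block_size=block_size)
        for (a, b, c), s in zip(buf, scores):
            yield a, b, c, float(s)

    for a, b, c in edges:
        if a in emb and b in emb:
            buf.append((a, b, c))
        if len(buf) >= block_size:
            yield from flush()
            buf = []
    if buf:
        yield from flush()
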