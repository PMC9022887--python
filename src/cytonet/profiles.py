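"""Disease-specific cytokine profiles.

For each disease, the mean Association Score between its gene set and every
catalog cytokine gives a raw profile; raw averages are then normalised to
NAAS (normalised average Association Scores) by an empirical-CDF rank taken
within the disease's size bin: diseases are binned by gene-set size
(2-9, 10-19, 20-49, >49) and

    NAAS(d, c) = #{diseases e in d's bin : avg(e, c) < avg(d, c)} / bin size.

The inequality is strict, so the bin minimum maps to 0 and ties score 0
against each other.  Normalisation is per cytokine within the bin by
default (each cytokine gets its own empirical CDF), with a pooled mode
available.  Four Immune Scores summarise a profile as category means
(inflammation-related cytokines, chemokines, growth factors, other).

Cytokines themselves are hierarchically clustered by their association-score
vectors over all non-cytokine genes, and each cluster is annotated with a
signature set of non-cytokine genes that associate preferentially with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata

from .association import block_scores
from .embedding import EmbeddedNetwork
from .errors import InvalidParameterError
from .netio import CytokineCatalog, DiseaseGeneSet, CATEGORIES

logger = logging.getLogger(__name__)

#: gene-set size bins (inclusive bounds; the last is open above)
BINS = (("2-9", 2, 9), ("10-19", 10, 19), ("20-49", 20, 49), (">49", 50, None))


def non_cytokine_count(universe_size: int, n_cytokines: int) -> int:
    """Number of non-cytokine genes in the universe."""
    if n_cytokines > universe_size:
        raise InvalidParameterError(
            f"{n_cytokines} cytokines cannot exceed universe of {universe_size}"
        )
    return universe_size - n_cytokines


def assign_bin(n_genes: int) -> str:
    """Size bin for a disease with ``n_genes`` associated genes."""
    if n_genes < 2:
        raise InvalidParameterError(f"disease sets have >= 2 genes, got {n_genes}")
    for name, lo, hi in BINS:
        if n_genes >= lo and (hi is None or n_genes <= hi):
            return name
    raise AssertionError("unreachable")


@dataclass
class RawProfile:
    """Mean Association Score between a disease's genes and each cytokine."""

    disease_id: str
    avg_score: pd.Series  # indexed by cytokine, values in [-1, 1]
    n_genes: int

    @property
    def bin_id(self) -> str:
        return assign_bin(self.n_genes)


@dataclass
class CytokineProfile:
    """A disease's NAAS vector (values in [0, 1]) and its size bin."""

    disease_id: str
    naas: pd.Series  # indexed by cytokine
    bin_id: str
    n_genes: int


def raw_profile(
    emb: EmbeddedNetwork,
    disease: DiseaseGeneSet,
    catalog: CytokineCatalog,
    exclude_self: bool = True,
) -> RawProfile:
    """Average Association Score between the disease's genes and each cytokine.

    When a cytokine is itself in the disease set, its trivial self-similarity
    of 1 is excluded from its own average (``exclude_self``); the average is
    then over the remaining genes.
    """
    genes = sorted(disease.genes)
    cytos = list(catalog.cytokines)
    scores = block_scores(emb, genes, cytos)  # (n_genes, n_cyto)
    sums = scores.sum(axis=0)
    n = len(genes)
    counts = np.full(len(cytos), n, dtype=float)
    if exclude_self:
        gene_pos = {g: i for i, g in enumerate(genes)}
        for j, c in enumerate(cytos):
            i = gene_pos.get(c)
            if i is not None and n > 1:
                sums[j] -= scores[i, j]
                counts[j] -= 1
    avg = pd.Series(sums / counts, index=cytos)
    return RawProfile(disease_id=disease.disease_id, avg_score=avg, n_genes=n)


def raw_profiles(
    emb: EmbeddedNetwork,
    diseases: Sequence[DiseaseGeneSet],
    catalog: CytokineCatalog,
    exclude_self: bool = True,
) -> list[RawProfile]:
    return [raw_profile(emb, d, catalog, exclude_self=exclude_self) for d in diseases]


def naas_normalize(
    profiles: Sequence[RawProfile],
    mode: Literal["per-cytokine", "pooled"] = "per-cytokine",
) -> list[CytokineProfile]:
    """Empirical-CDF normalisation of raw averages within each size bin.

    ``per-cytokine`` (default): each cytokine's averages are ranked against
    the same cytokine's averages across the diseases of the bin, dividing by
    the bin size.  ``pooled``: all (disease, cytokine) averages of the bin
    form one reference distribution, dividing by the pooled count.
    """
    if not profiles:
        return []
    by_bin: dict[str, list[RawProfile]] = {}
    for p in profiles:
        by_bin.setdefault(p.bin_id, []).append(p)
    cytos = profiles[0].avg_score.index
    out: dict[str, CytokineProfile] = {}
    for bin_id, members in by_bin.items():
        m = len(members)
        mat = np.vstack([p.avg_score.to_numpy() for p in members])  # (m, n_cyto)
        if mode == "per-cytokine":
            # rank 'min' - 1 == number of strictly smaller values in the column
            less = rankdata(mat, method="min", axis=0) - 1
            naas = less / m
        elif mode == "pooled":
            flat = np.sort(mat, axis=None)
            less = np.searchsorted(flat, mat.ravel(), side="left").reshape(mat.shape)
            naas = less / flat.size
        else:
            raise InvalidParameterError(f"unknown NAAS mode {mode!r}")
        for p, row in zip(members, naas):
            out[p.disease_id] = CytokineProfile(
                disease_id=p.disease_id,
                naas=pd.Series(row, index=cytos),
                bin_id=bin_id,
                n_genes=p.n_genes,
            )
    return [out[p.disease_id] for p in profiles]


@dataclass
class ImmuneScores:
    """Category means of a disease's NAAS (absent categories are None)."""

    disease_id: str
    scores: dict  # category -> float | None


def immune_scores(profile: CytokineProfile, catalog: CytokineCatalog) -> ImmuneScores:
    by_cat = catalog.by_category()
    out: dict[str, float | None] = {}
    for cat in CATEGORIES:
        members = by_cat[cat]
        if not members:
            logger.warning("category %r has no cytokines; Immune Score absent", cat)
            out[cat] = None
            continue
        out[cat] = float(profile.naas.loc[members].mean())
    return ImmuneScores(disease_id=profile.disease_id, scores=out)


def profiles_frame(profiles: Sequence[CytokineProfile]) -> pd.DataFrame:
    """Diseases x cytokines NAAS matrix (plus bin and size columns)."""
    df = pd.DataFrame({p.disease_id: p.naas for p in profiles}).T
    df.index.name = "disease_id"
    df.insert(0, "n_genes", [p.n_genes for p in profiles])
    df.insert(1, "bin", [p.bin_id for p in profiles])
    return df


# ---------------------------------------------------------------------------
# cytokine clustering and signature genes
# ---------------------------------------------------------------------------


@dataclass
class CytokineClustering:
    """Hierarchical clustering of cytokines by genome-wide association vectors."""

    cytokines: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix
    labels: dict  # cytokine -> cluster id (1..k)
    signatures: dict = field(default_factory=dict)  # cluster id -> sorted gene list
    unassigned: tuple[str, ...] = ()  # genes below the assignment floor
    n_zero_height_merges: int = 0

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return self.cytokines[node.id]
            l, r = rec(node.left), rec(node.right)
            return f"({l}:{node.dist - node.left.dist:.6g},{r}:{node.dist - node.right.dist:.6g})"

        return rec(tree) + ";"


def cluster_cytokines(
    emb: EmbeddedNetwork,
    catalog: CytokineCatalog,
    universe: Sequence[str],
    k: int = 6,
    linkage_method: str = "average",
    distance_metric: str = "correlation",
    signature_margin: float = 0.0,
    assignment_floor: float = 0.4,
) -> CytokineClustering:
    """Cluster cytokines by their association vectors over non-cytokine genes.

    The tree is cut to ``k`` clusters; each non-cytokine gene is assigned to
    the cluster with which its mean association is highest, provided that
    mean is at least ``assignment_floor`` and beats every other cluster by
    ``signature_margin`` — otherwise the gene is left unassigned (the
    distant, "BLU"-style class).
    """
    cytos = [c for c in catalog.cytokines if c in emb]
    if k < 1 or k > len(cytos):
        raise InvalidParameterError(f"k={k} incompatible with {len(cytos)} cytokines")
    cyto_set = set(catalog.cytokines)
    background = [g for g in universe if g not in cyto_set and g in emb]
    if not background:
        raise InvalidParameterError("no non-cytokine genes to cluster against")
    vectors = block_scores(emb, cytos, background)  # (n_cyto, n_background)
    # correlation distance degenerates on constant vectors; fall back to euclidean
    if distance_metric == "correlation" and np.any(vectors.std(axis=1) == 0):
        logger.warning("constant association vector(s); using euclidean distance")
        distance_metric = "euclidean"
    link = hierarchy.linkage(vectors, method=linkage_method, metric=distance_metric)
    n_zero = int(np.sum(link[:, 2] <= 1e-12))
    if n_zero:
        logger.warning("%d zero-height merges (identical association vectors)", n_zero)
    flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
    labels = {c: int(l) for c, l in zip(cytos, flat)}

    cluster_ids = sorted(set(flat))
    means = np.vstack(
        [vectors[flat == cid].mean(axis=0) for cid in cluster_ids]
    )  # (k, n_background)
    order = np.argsort(-means, axis=0)
    best, second = order[0], order[1] if len(cluster_ids) > 1 else order[0]
    best_val = means[best, np.arange(means.shape[1])]
    second_val = (
        means[second, np.arange(means.shape[1])] if len(cluster_ids) > 1 else np.full(means.shape[1], -np.inf)
    )
    signatures: dict[int, list[str]] = {cid: [] for cid in cluster_ids}
    unassigned = []
    for j, g in enumerate(background):
        if best_val[j] >= assignment_floor and best_val[j] - second_val[j] > signature_margin:
            signatures[cluster_ids[best[j]]].append(g)
        else:
            unassigned.append(g)
    return CytokineClustering(
        cytokines=tuple(cytos),
        linkage=link,
        labels=labels,
        signatures={cid: sorted(g) for cid, g in signatures.items()},
        unassigned=tuple(unassigned),
        n_zero_height_merges=n_zero,
    )
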