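"""Disease subnetworks, Immune Connection Density, and spectral partition.

For a disease, the subnetwork keeps only high-confidence predicted links
(Association Score strictly above a cutoff, default 0.8) between the
disease's pathogenesis genes — labelled cytokine receptors or
disease-specific — and the catalog cytokines.  Edges among pathogenesis
genes or among cytokines are never included; disease genes that are
themselves cytokines sit on the cytokine side only.

Immune Connection Density summarises such a bipartite subnetwork:

    ICD = (1 / (Np * Ni)) * sum over retained edges of d_pi

with Np pathogenesis genes, Ni cytokines and d_pi the edge's Association
Score (a pure edge-count mode treats each edge as 1).

The graph-Laplacian Fiedler vector of the subnetwork drives a sign cut:
nodes with positive entries form the well-connected class, negative entries
the poorly connected class, and near-zero entries the articulation class.
The pathogenesis genes in the well-connected class are the disease's key
genes mediating cytokine connections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import eigsh

from .association import block_scores
from .embedding import EmbeddedNetwork
from .errors import InvalidParameterError, NumericalError
from .netio import CytokineCatalog, DiseaseGeneSet

logger = logging.getLogger(__name__)

RECEPTOR = "receptor"
DISEASE_SPECIFIC = "disease_specific"

WELL = "well_connected"
POOR = "poorly_connected"
ARTICULATION = "articulation"

_DENSE_LIMIT = 500
_NULL_TOL = 1e-8  # relative to the largest eigenvalue


@dataclass
class DiseaseSubnetwork:
    """Bipartite pathogenesis-gene / cytokine graph above the score cutoff."""

    disease_id: str
    pathogenesis_label: dict  # gene -> RECEPTOR | DISEASE_SPECIFIC
    cytokine_nodes: tuple[str, ...]
    edges: tuple  # (pathogenesis gene, cytokine, d_pi)
    cutoff: float = 0.8

    @property
    def np_(self) -> int:
        """Np: pathogenesis genes in the subnetwork."""
        return len(self.pathogenesis_label)

    @property
    def ni(self) -> int:
        """Ni: cytokines in the subnetwork."""
        return len(self.cytokine_nodes)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.pathogenesis_label)) + self.cytokine_nodes

    def is_empty(self) -> bool:
        return not self.edges

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for gene, label in self.pathogenesis_label.items():
            g.add_node(gene, kind=label)
        for c in self.cytokine_nodes:
            g.add_node(c, kind="cytokine")
        for a, c, w in self.edges:
            g.add_edge(a, c, weight=w)
        return g


def build_subnetwork(
    emb: EmbeddedNetwork,
    disease: DiseaseGeneSet,
    catalog: CytokineCatalog,
    cutoff: float = 0.8,
) -> DiseaseSubnetwork:
    """Retain pathogenesis-gene-to-cytokine pairs with score > ``cutoff``.

    Only nodes incident to at least one retained edge remain.  A no-edge
    result is a valid empty subnetwork (ICD 0).
    """
    cyto_set = set(catalog.cytokines)
    patho = sorted(g for g in disease.genes if g not in cyto_set and g in emb)
    cytos = [c for c in catalog.cytokines if c in emb]
    if (set(disease.genes) & cyto_set):
        logger.info(
            "disease %s: %d gene(s) are catalog cytokines; placed on the cytokine side",
            disease.disease_id,
            len(set(disease.genes) & cyto_set),
        )
    if not patho or not cytos:
        return DiseaseSubnetwork(disease.disease_id, {}, (), (), cutoff)
    scores = block_scores(emb, patho, cytos)
    keep = scores > cutoff
    edges = tuple(
        (patho[i], cytos[j], float(scores[i, j]))
        for i, j in zip(*np.nonzero(keep))
    )
    kept_patho = {a for a, _, _ in edges}
    kept_cytos = tuple(c for c in cytos if any(e[1] == c for e in edges))
    labels = {
        g: (RECEPTOR if g in catalog.receptors else DISEASE_SPECIFIC) for g in sorted(kept_patho)
    }
    return DiseaseSubnetwork(disease.disease_id, labels, kept_cytos, edges, cutoff)


def icd(sub: DiseaseSubnetwork, mode: Literal["score", "count"] = "score") -> float:
    """Immune Connection Density: sum of cross-type edge weights over Np*Ni."""
    if sub.is_empty():
        return 0.0
    total = sum((w if mode == "score" else 1.0) for _, _, w in sub.edges)
    return total / (sub.np_ * sub.ni)


@dataclass
class CytokineRecall:
    recognized: int
    known: int
    recall: float | None


def cytokine_recall(
    disease: DiseaseGeneSet, sub: DiseaseSubnetwork, catalog: CytokineCatalog
) -> CytokineRecall:
    """Of the catalog cytokines in the disease's own gene set, the fraction
    present as cytokine nodes of the predicted subnetwork."""
    known = sorted(set(disease.genes) & set(catalog.cytokines))
    if not known:
        return CytokineRecall(0, 0, None)
    present = set(sub.cytokine_nodes)
    rec = sum(1 for c in known if c in present)
    return CytokineRecall(rec, len(known), rec / len(known))


# ---------------------------------------------------------------------------
# spectral partition
# ---------------------------------------------------------------------------


@dataclass
class PartitionResult:
    """Fiedler sign-cut of a disease subnetwork."""

    fiedler_value: float
    fiedler_vector: np.ndarray
    nodes: tuple[str, ...]
    classes: dict  # node -> WELL | POOR | ARTICULATION
    key_genes: tuple[str, ...]  # pathogenesis genes in the well-connected class

    def members(self, cls: str) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self.classes[n] == cls)


def _laplacian_spectrum(adj: np.ndarray, sparse: bool):
    lap = np.diag(adj.sum(axis=1)) - adj
    n = lap.shape[0]
    if not sparse:
        return eigh(lap)
    k = min(max(3, 8), n - 1)
    try:
        vals, vecs = eigsh(csr_matrix(lap), k=k, which="SA")
    except Exception as exc:  # pragma: no cover - solver failure surface
        raise NumericalError(f"sparse eigensolver failed: {exc}") from exc
    order = np.argsort(vals)
    return vals[order], vecs[:, order]


def fiedler_partition(
    sub: DiseaseSubnetwork | None = None,
    articulation_tol: float | None = None,
    weighted: bool = False,
    nodes: Sequence[str] | None = None,
    edges: Sequence[tuple[str, str, float]] | None = None,
    pathogenesis: Sequence[str] | None = None,
) -> PartitionResult:
    """Sign cut on the Fiedler vector of the subnetwork Laplacian.

    The Laplacian is unweighted by default (an edge counts 1 regardless of
    its Association Score); ``weighted`` switches to d_pi edge weights.  For
    a connected graph the Fiedler value is the smallest non-null Laplacian
    eigenvalue and its eigenvector drives the cut; for a disconnected graph
    the zero eigenvalue is degenerate and the cut separates components
    exactly (Fiedler value 0).  The sign orientation is fixed so the
    well-connected (positive) class carries the larger total degree; entries
    within ``articulation_tol`` of zero (default 1e-6 x max|w|) form the
    articulation class.

    Accepts either a :class:`DiseaseSubnetwork` or explicit ``nodes`` /
    ``edges`` / ``pathogenesis`` lists.
    """
    if sub is not None:
        node_list = list(sub.nodes)
        edge_list = list(sub.edges)
        patho_set = set(sub.pathogenesis_label)
    else:
        if nodes is None or edges is None:
            raise InvalidParameterError("need a subnetwork or explicit nodes+edges")
        node_list = list(nodes)
        edge_list = list(edges)
        patho_set = set(pathogenesis or ())
    n = len(node_list)
    if n < 2:
        raise InvalidParameterError(f"partition needs >= 2 nodes, got {n}")
    idx = {g: i for i, g in enumerate(node_list)}
    adj = np.zeros((n, n))
    for a, b, w in edge_list:
        ww = float(w) if weighted else 1.0
        adj[idx[a], idx[b]] = ww
        adj[idx[b], idx[a]] = ww

    vals, vecs = _laplacian_spectrum(adj, sparse=n > _DENSE_LIMIT)
    scale = max(vals[-1], 1.0)
    null_mask = vals < _NULL_TOL * scale
    n_null = int(np.sum(null_mask))
    if n_null >= 2:
        # disconnected graph: the component-separating vector lives in the
        # null space; take the null-space direction orthogonal to constants
        basis = vecs[:, null_mask]
        ones = np.ones(n) / np.sqrt(n)
        proj = basis - np.outer(ones, ones @ basis)
        norms = np.linalg.norm(proj, axis=0)
        w = proj[:, int(np.argmax(norms))]
        w /= np.linalg.norm(w)
        fiedler_value = 0.0
    else:
        pos = int(np.argmax(~null_mask))
        fiedler_value = float(vals[pos])
        w = vecs[:, pos].copy()

    tol = articulation_tol if articulation_tol is not None else 1e-6 * np.max(np.abs(w))
    degrees = adj.sum(axis=1)
    deg_pos = degrees[w > tol].sum()
    deg_neg = degrees[w < -tol].sum()
    flip = deg_pos < deg_neg or (
        deg_pos == deg_neg and int(np.sum(w > tol)) < int(np.sum(w < -tol))
    )
    if flip:
        w = -w
    classes = {}
    for g, wi in zip(node_list, w):
        if wi > tol:
            classes[g] = WELL
        elif wi < -tol:
            classes[g] = POOR
        else:
            classes[g] = ARTICULATION
    key = tuple(g for g in sorted(patho_set) if classes.get(g) == WELL)
    return PartitionResult(
        fiedler_value=fiedler_value,
        fiedler_vector=w,
        nodes=tuple(node_list),
        classes=classes,
        key_genes=key,
    )


def partition_summary(
    entries: Sequence[tuple[DiseaseGeneSet, DiseaseSubnetwork, PartitionResult]],
) -> pd.DataFrame:
    """Per-disease table of the well-connected module's composition.

    Columns mirror a per-disease report: receptor and disease-specific gene
    counts in the well-connected class, and the percentage of the disease's
    input gene set retained there (one decimal place).
    """
    rows = []
    for disease, sub, part in entries:
        well = set(part.members(WELL))
        receptors = sum(
            1 for g, lab in sub.pathogenesis_label.items() if lab == RECEPTOR and g in well
        )
        disease_genes = sum(
            1
            for g, lab in sub.pathogenesis_label.items()
            if lab == DISEASE_SPECIFIC and g in well
        )
        n_input = disease.n_genes
        pct = round(100.0 * disease_genes / n_input, 1) if n_input else 0.0
        rows.append(
            {
                "disease_id": disease.disease_id,
                "receptors_in_module": receptors,
                "disease_genes_in_module": disease_genes,
                "input_genes": n_input,
                "pct_retained": pct,
                "fiedler_value": part.fiedler_value,
            }
        )
    return pd.DataFrame(rows)


def retained_percent(n_retained: int, n_input: int) -> float:
    """Percentage of input genes retained in the well-connected module
    (one decimal place)."""
    if n_input < 1:
        raise InvalidParameterError("n_input must be >= 1")
    return round(100.0 * n_retained / n_input, 1)
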