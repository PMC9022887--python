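"""Tabular input/output and network filtering.

The pipeline consumes four plain TSV tables:

* edge list          ``gene1<TAB>gene2<TAB>combined_score`` (STRING-style,
  integer confidence on a 0-1000 scale)
* disease-gene table ``disease_id<TAB>gene``
* cytokine catalog   ``gene<TAB>category<TAB>receptor`` where category is one
  of ``inflammation``, ``chemokine``, ``growth_factor``, ``other`` for
  cytokines, or ``-`` for pure receptor rows; receptor is 0/1
* frequency table    ``disease_id<TAB>cytokine<TAB>frequency``

All readers tolerate one optional header line, detected by a non-numeric
value in the numeric column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputFormatError, InvalidParameterError

logger = logging.getLogger(__name__)

CATEGORIES = ("inflammation", "chemokine", "growth_factor", "other")

#: STRING-style confidence scale.
MAX_CONFIDENCE = 1000


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class WeightedNetwork:
    """Undirected gene network with per-edge integer confidence in [0, 1000].

    Each undirected edge is stored exactly once under the canonical
    (lexicographically sorted) gene ordering; self-loops are disallowed.
    """

    genes: tuple[str, ...]
    edges: tuple[tuple[str, str, int], ...]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, int]], extra_genes: Iterable[str] = ()
    ) -> "WeightedNetwork":
        """Canonicalize an edge iterable.

        Duplicate pairs are collapsed keeping the maximum confidence (order
        insensitive, so symmetric exports collapse cleanly); self-loops are
        dropped with a logged warning.
        """
        best: dict[tuple[str, str], int] = {}
        genes: set[str] = set(extra_genes)
        n_loops = 0
        for a, b, c in edges:
            c = int(c)
            if not 0 <= c <= MAX_CONFIDENCE:
                raise InputFormatError(
                    f"confidence {c} for pair ({a}, {b}) outside [0, {MAX_CONFIDENCE}]"
                )
            if a == b:
                n_loops += 1
                continue
            key = _canonical(a, b)
            if c > best.get(key, -1):
                best[key] = c
            genes.update(key)
        if n_loops:
            logger.warning("dropped %d self-loop(s)", n_loops)
        edge_tuple = tuple(sorted((a, b, c) for (a, b), c in best.items()))
        return cls(genes=tuple(sorted(genes)), edges=edge_tuple)

    def neighbors(self) -> dict[str, list[str]]:
        """Adjacency lists, each neighbor list sorted."""
        adj: dict[str, list[str]] = {g: [] for g in self.genes}
        for a, b, _ in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        for lst in adj.values():
            lst.sort()
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genes)
        g.add_weighted_edges_from(self.edges, weight="confidence")
        return g


@dataclass(frozen=True)
class DiseaseGeneSet:
    """A disease and its associated genes (at least two, all in the universe)."""

    disease_id: str
    genes: frozenset[str]

    def __post_init__(self):
        if len(self.genes) < 2:
            raise InvalidParameterError(
                f"disease {self.disease_id!r} has {len(self.genes)} gene(s); need >= 2"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class CytokineCatalog:
    """The cytokine list, its four-way categorisation, and the receptor list.

    ``category`` maps every cytokine to one of :data:`CATEGORIES`; the
    receptor set is disjoint from the cytokine list.
    """

    cytokines: tuple[str, ...]
    category: Mapping[str, str] = field(default_factory=dict)
    receptors: frozenset[str] = frozenset()

    def __post_init__(self):
        missing = [c for c in self.cytokines if c not in self.category]
        if missing:
            raise InvalidParameterError(f"cytokines without category: {missing[:5]}")
        bad = [c for c, cat in self.category.items() if cat not in CATEGORIES]
        if bad:
            raise InvalidParameterError(f"unknown categories for: {bad[:5]}")
        overlap = set(self.cytokines) & self.receptors
        if overlap:
            raise InvalidParameterError(
                f"receptors must be disjoint from cytokines; overlap: {sorted(overlap)[:5]}"
            )

    @property
    def n_cytokines(self) -> int:
        return len(self.cytokines)

    def by_category(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {cat: [] for cat in CATEGORIES}
        for c in self.cytokines:
            out[self.category[c]].append(c)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_rows(path, n_fields: int, numeric_col: int | None):
    """Yield (lineno, fields) from a whitespace/tab-delimited file.

    A single leading header line is skipped when the numeric column does not
    parse as a number.
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < n_fields:
                raise InputFormatError(
                    f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}"
                )
            if lineno == 1 and numeric_col is not None:
                try:
                    float(fields[numeric_col])
                except ValueError:
                    continue  # header
            yield lineno, fields


def read_edge_list(path, score_scale: int = MAX_CONFIDENCE) -> WeightedNetwork:
    """Read a STRING-style edge list into a canonical :class:`WeightedNetwork`.

    ``score_scale`` rescales confidences given on another scale (e.g. 1 for
    scores already in [0, 1]) onto the integer 0-1000 scale.
    """
    edges = []
    for lineno, fields in _read_rows(path, 3, numeric_col=2):
        a, b, raw = fields[0], fields[1], fields[2]
        try:
            score = float(raw)
        except ValueError as exc:
            raise InputFormatError(f"{path}:{lineno}: unparseable score {raw!r}") from exc
        conf = score * (MAX_CONFIDENCE / score_scale)
        conf_int = int(round(conf))
        if not 0 <= conf_int <= MAX_CONFIDENCE:
            raise InputFormatError(
                f"{path}:{lineno}: confidence {raw} outside [0, {score_scale}]"
            )
        edges.append((a, b, conf_int))
    return WeightedNetwork.from_edges(edges)


def write_edge_list(net: WeightedNetwork, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene1\tgene2\tcombined_score\n")
        for a, b, c in net.edges:
            fh.write(f"{a}\t{b}\t{c}\n")


def filter_high_confidence(net: WeightedNetwork, cutoff: int = 800) -> WeightedNetwork:
    """Retain edges with confidence >= ``cutoff`` (the cutoff is inclusive:
    edges *below* the cutoff are the ones excluded)."""
    kept = tuple(e for e in net.edges if e[2] >= cutoff)
    genes: set[str] = set()
    for a, b, _ in kept:
        genes.add(a)
        genes.add(b)
    return WeightedNetwork(genes=tuple(sorted(genes)), edges=kept)


def select_universe(net_high: WeightedNetwork) -> tuple[str, ...]:
    """Genes incident to at least one retained edge, lexicographically ordered."""
    genes: set[str] = set()
    for a, b, _ in net_high.edges:
        genes.add(a)
        genes.add(b)
    return tuple(sorted(genes))


def read_disease_sets(path, universe: Sequence[str]) -> list[DiseaseGeneSet]:
    """Read a disease-gene TSV, intersect with the universe, and keep diseases
    with at least two surviving genes (the number dropped is logged)."""
    uni = set(universe)
    per_disease: dict[str, set[str]] = {}
    for _, fields in _read_rows(path, 2, numeric_col=None):
        disease, gene = fields[0], fields[1]
        if disease == "disease_id" and gene == "gene":
            continue  # header
        per_disease.setdefault(disease, set()).add(gene)
    sets = []
    n_dropped = 0
    for disease in sorted(per_disease):
        genes = per_disease[disease] & uni
        if len(genes) < 2:
            n_dropped += 1
            continue
        sets.append(DiseaseGeneSet(disease_id=disease, genes=frozenset(genes)))
    if n_dropped:
        logger.info("dropped %d disease(s) with < 2 genes in the universe", n_dropped)
    return sets


def write_disease_sets(sets: Iterable[DiseaseGeneSet], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("disease_id\tgene\n")
        for ds in sets:
            for g in sorted(ds.genes):
                fh.write(f"{ds.disease_id}\t{g}\n")


def read_catalog(path) -> CytokineCatalog:
    cytokines: list[str] = []
    category: dict[str, str] = {}
    receptors: set[str] = set()
    for lineno, fields in _read_rows(path, 3, numeric_col=2):
        gene, cat, flag = fields[0], fields[1], fields[2]
        if flag not in ("0", "1"):
            raise InputFormatError(f"{path}:{lineno}: receptor flag must be 0/1, got {flag!r}")
        if flag == "1":
            receptors.add(gene)
        elif cat in CATEGORIES:
            cytokines.append(gene)
            category[gene] = cat
        else:
            raise InputFormatError(f"{path}:{lineno}: unknown category {cat!r}")
    return CytokineCatalog(
        cytokines=tuple(cytokines), category=category, receptors=frozenset(receptors)
    )


def write_catalog(catalog: CytokineCatalog, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tcategory\treceptor\n")
        for c in catalog.cytokines:
            fh.write(f"{c}\t{catalog.category[c]}\t0\n")
        for r in sorted(catalog.receptors):
            fh.write(f"{r}\t-\t1\n")


def read_frequency_table(path) -> pd.DataFrame:
    """Read a literature co-occurrence frequency table.

    Returns a long-format DataFrame with columns ``disease_id``, ``cytokine``,
    ``frequency``; only sampled (present) entries appear.
    """
    rows = []
    for lineno, fields in _read_rows(path, 3, numeric_col=2):
        try:
            freq = float(fields[2])
        except ValueError as exc:
            raise InputFormatError(
                f"{path}:{lineno}: unparseable frequency {fields[2]!r}"
            ) from exc
        rows.append((fields[0], fields[1], freq))
    df = pd.DataFrame(rows, columns=["disease_id", "cytokine", "frequency"])
    return df.sort_values(["disease_id", "cytokine"], ignore_index=True)


def write_frequency_table(freq: pd.DataFrame, path) -> None:
    out = freq.sort_values(["disease_id", "cytokine"])
    out.to_csv(path, sep="\t", index=False, columns=["disease_id", "cytokine", "frequency"])
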