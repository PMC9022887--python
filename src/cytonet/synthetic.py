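"""Synthetic inputs with the statistical structure the analysis assumes.

Real runs consume four external tables (a STRING-like weighted edge list, a
DisGeNET-like disease-gene table, a cytokine catalog and a literature
co-occurrence frequency table).  This module fabricates all four so the full
pipeline is testable offline:

* a planted-partition gene network with dense functional modules
  (within-module edge probability p_in >> between-module p_out) and a
  STRING-like bimodal confidence distribution — within-module edges draw
  confidences in 800..1000, between-module in 150..799, reproducing the
  high/low-confidence dichotomy at the 800 cutoff;
* cytokine genes planted as members of a few modules ("families"), so the
  cytokine-clustering stage has a ground truth to recover;
* disease gene sets with the size-bin structure 2-9 / 10-19 / 20-49 / >49;
  a configurable fraction of diseases is *enriched* — most of its genes come
  from one cytokine family's module, planting a true disease-cytokine
  affinity;
* literature frequencies equal to the true affinity plus Gaussian noise
  (identity monotone link), with a dropout fraction left unsampled.

All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .netio import (
    CATEGORIES,
    CytokineCatalog,
    DiseaseGeneSet,
    WeightedNetwork,
    write_catalog,
    write_disease_sets,
    write_edge_list,
    write_frequency_table,
)


@dataclass(frozen=True)
class ConfidenceModel:
    """Edge-confidence distribution: uniform integer ranges for within- and
    between-module edges (inclusive bounds)."""

    within_lo: int = 800
    within_hi: int = 1000
    between_lo: int = 150
    between_hi: int = 799

    def draw(self, rng: np.random.Generator, within: bool, size: int) -> np.ndarray:
        lo, hi = (self.within_lo, self.within_hi) if within else (self.between_lo, self.between_hi)
        return rng.integers(lo, hi + 1, size=size)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def make_modular_network(
    module_sizes: Sequence[int],
    p_in: float,
    p_out: float,
    confidence_model: ConfidenceModel | None = None,
    seed: int = 0,
    gene_names: Sequence[str] | None = None,
) -> tuple[WeightedNetwork, dict]:
    """Planted-partition graph with module-dependent edge confidences.

    Returns the network and the gene -> module-id assignment.  Requires
    p_in > p_out so the planted structure is recoverable.
    """
    if p_in <= p_out:
        raise InvalidParameterError(f"p_in ({p_in}) must exceed p_out ({p_out})")
    if any(s < 2 for s in module_sizes):
        raise InvalidParameterError("every module needs >= 2 genes")
    cm = confidence_model or ConfidenceModel()
    n = int(sum(module_sizes))
    names = list(gene_names) if gene_names is not None else _gene_names(n)
    if len(names) != n:
        raise InvalidParameterError("gene_names length must equal total module size")
    module_of = np.repeat(np.arange(len(module_sizes)), module_sizes)
    rng = np.random.default_rng(seed)

    iu, ju = np.triu_indices(n, k=1)
    within = module_of[iu] == module_of[ju]
    prob = np.where(within, p_in, p_out)
    present = rng.random(len(iu)) < prob
    iu, ju, within = iu[present], ju[present], within[present]
    conf = np.empty(len(iu), dtype=np.int64)
    conf[within] = cm.draw(rng, True, int(within.sum()))
    conf[~within] = cm.draw(rng, False, int((~within).sum()))
    edges = [(names[a], names[b], int(c)) for a, b, c in zip(iu, ju, conf)]
    net = WeightedNetwork.from_edges(edges, extra_genes=names)
    assignment = {names[i]: int(module_of[i]) for i in range(n)}
    return net, assignment


#: inclusive size ranges of the four disease bins
_BIN_RANGES = ((2, 9), (10, 19), (20, 49), (50, 120))

#: bin-1 proportion 0.42 mirrors the reported predominance of small sets
DEFAULT_BIN_MIX = (0.42, 0.28, 0.18, 0.12)


def make_disease_sets(
    n_diseases: int,
    bin_mix: Sequence[float],
    gene_universe: Sequence[str],
    seed: int = 0,
    module_assignment: dict | None = None,
    enriched_targets: Sequence[int | None] | None = None,
    purity: float = 0.9,
    max_large: int = 120,
) -> list[DiseaseGeneSet]:
    """Disease gene sets with the four-bin size structure.

    ``enriched_targets[i]`` (optional) names the module from which disease i
    draws a ``purity`` fraction of its genes, planting an affinity to the
    cytokines of that module; ``None`` entries are unenriched (uniform draw).
    """
    if abs(sum(bin_mix) - 1.0) > 1e-9 or len(bin_mix) != 4:
        raise InvalidParameterError("bin_mix must be 4 proportions summing to 1")
    universe = list(gene_universe)
    ranges = ((2, 9), (10, 19), (20, 49), (50, max_large))
    for mix, (lo, hi) in zip(bin_mix, ranges):
        if n_diseases > 0 and mix > 0 and (lo > hi or hi > len(universe)):
            raise InvalidParameterError(
                f"bin {lo}-{hi} unusable with a universe of {len(universe)} genes"
            )
    rng = np.random.default_rng(seed)
    universe_arr = np.array(universe)
    by_module: dict[int, np.ndarray] = {}
    if module_assignment is not None:
        mods: dict[int, list[str]] = {}
        for g in universe:
            m = module_assignment.get(g)
            if m is not None:
                mods.setdefault(m, []).append(g)
        by_module = {m: np.array(sorted(gs)) for m, gs in mods.items()}

    out = []
    width = max(3, len(str(n_diseases)))
    for i in range(n_diseases):
        b = int(rng.choice(4, p=np.asarray(bin_mix, dtype=float)))
        lo, hi = ranges[b]
        size = int(rng.integers(lo, hi + 1))
        target = enriched_targets[i] if enriched_targets is not None else None
        if target is not None and target in by_module:
            pool = by_module[target]
            n_core = min(len(pool), max(1, int(round(purity * size))))
            core = rng.choice(pool, size=n_core, replace=False)
            rest_pool = np.array([g for g in universe_arr if g not in set(core)])
            rest = rng.choice(rest_pool, size=size - n_core, replace=False)
            genes = frozenset(core) | frozenset(rest)
        else:
            genes = frozenset(rng.choice(universe_arr, size=size, replace=False))
        out.append(DiseaseGeneSet(disease_id=f"D{i:0{width}d}", genes=genes))
    return out


def make_cytokine_catalog(
    module_assignment: dict,
    cytokine_modules: Sequence[int],
    per_module: int = 10,
    n_receptors_per_module: int = 5,
    seed: int = 0,
) -> tuple[CytokineCatalog, dict]:
    """Plant cytokines inside the chosen modules.

    The first ``per_module`` genes of each listed module become cytokines of
    one category (modules cycle through the four categories); the next
    ``n_receptors_per_module`` genes become receptors.  Returns the catalog
    and cytokine -> family(module) map.
    """
    by_module: dict[int, list[str]] = {}
    for g, m in module_assignment.items():
        by_module.setdefault(m, []).append(g)
    for gs in by_module.values():
        gs.sort()
    cytokines, category, receptors, family = [], {}, set(), {}
    for fam_idx, m in enumerate(cytokine_modules):
        pool = by_module.get(m, [])
        need = per_module + n_receptors_per_module
        if len(pool) < need:
            raise InvalidParameterError(f"module {m} has {len(pool)} genes; need {need}")
        cat = CATEGORIES[fam_idx % len(CATEGORIES)]
        for g in pool[:per_module]:
            cytokines.append(g)
            category[g] = cat
            family[g] = m
        receptors.update(pool[per_module : per_module + n_receptors_per_module])
    return (
        CytokineCatalog(
            cytokines=tuple(cytokines), category=category, receptors=frozenset(receptors)
        ),
        family,
    )


def true_affinity_matrix(
    disease_sets: Sequence[DiseaseGeneSet],
    module_assignment: dict,
    cytokine_family: dict,
) -> pd.DataFrame:
    """Planted disease x cytokine affinity: the fraction of the disease's
    genes lying in the cytokine's home module (a value in [0, 1])."""
    cytos = sorted(cytokine_family)
    rows = {}
    for ds in disease_sets:
        mods = np.array([module_assignment.get(g, -1) for g in ds.genes])
        rows[ds.disease_id] = [float(np.mean(mods == cytokine_family[c])) for c in cytos]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cytos)


def make_literature_freq(
    true_affinity: pd.DataFrame,
    noise_sd: float = 0.05,
    dropout: float = 0.1,
    seed: int = 0,
    monotone: Callable[[np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Literature co-occurrence frequencies from the planted affinity.

    freq = clip(monotone(affinity) + N(0, noise_sd), 0, 1); a ``dropout``
    fraction of entries is unsampled and omitted from the long-format output.
    The default monotone link is the identity.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if not 0 <= dropout < 1:
        raise InvalidParameterError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    vals = true_affinity.to_numpy(dtype=float)
    link = monotone or (lambda a: a)
    freq = link(vals)
    if noise_sd > 0:
        freq = freq + rng.normal(0.0, noise_sd, size=freq.shape)
    freq = np.clip(freq, 0.0, 1.0)
    sampled = rng.random(freq.shape) >= dropout
    rows = []
    for i, d in enumerate(true_affinity.index):
        for j, c in enumerate(true_affinity.columns):
            if sampled[i, j]:
                rows.append((d, c, float(freq[i, j])))
    return pd.DataFrame(rows, columns=["disease_id", "cytokine", "frequency"])


@dataclass
class SyntheticWorld:
    """A complete synthetic input set plus its ground truth."""

    network: WeightedNetwork
    module_assignment: dict
    catalog: CytokineCatalog
    cytokine_family: dict  # cytokine -> home module
    disease_sets: list
    enriched: dict  # disease_id -> target module (enriched diseases only)
    true_affinity: pd.DataFrame
    literature_freq: pd.DataFrame
    seed: int
    params: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_edge_list(self.network, outdir / "edges.tsv")
        write_disease_sets(self.disease_sets, outdir / "diseases.tsv")
        write_catalog(self.catalog, outdir / "catalog.tsv")
        write_frequency_table(self.literature_freq, outdir / "literature_freq.tsv")
        manifest = {
            "seed": self.seed,
            "n_genes": self.network.n_genes,
            "n_edges": self.network.n_edges,
            "n_cytokines": self.catalog.n_cytokines,
            "n_diseases": len(self.disease_sets),
            "enriched": self.enriched,
            **self.params,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def make_world(
    n_modules: int = 8,
    module_size: int = 62,
    n_cytokine_modules: int = 4,
    cytokines_per_module: int = 10,
    receptors_per_module: int = 5,
    n_diseases: int = 60,
    bin_mix: Sequence[float] = DEFAULT_BIN_MIX,
    p_in: float = 0.5,
    p_out: float = 0.01,
    enriched_fraction: float = 0.5,
    purity: float = 0.9,
    noise_sd: float = 0.05,
    dropout: float = 0.1,
    max_set_size: int = 120,
    seed: int = 0,
) -> SyntheticWorld:
    """Generate all four inputs for one world.

    Defaults give ~500 genes in 8 modules, 40 cytokines in 4 families, and
    60 diseases of which half are enriched for one cytokine family's module.
    """
    sizes = [module_size] * n_modules
    rng = np.random.default_rng(seed)
    net, assignment = make_modular_network(sizes, p_in, p_out, seed=int(rng.integers(2**31)))
    cyto_modules = list(range(n_cytokine_modules))
    catalog, family = make_cytokine_catalog(
        assignment,
        cyto_modules,
        per_module=cytokines_per_module,
        n_receptors_per_module=receptors_per_module,
        seed=seed,
    )
    n_enriched = int(round(enriched_fraction * n_diseases))
    targets: list[int | None] = [
        cyto_modules[i % len(cyto_modules)] if i < n_enriched else None
        for i in range(n_diseases)
    ]
    disease_sets = make_disease_sets(
        n_diseases,
        bin_mix,
        net.genes,
        seed=int(rng.integers(2**31)),
        module_assignment=assignment,
        enriched_targets=targets,
        purity=purity,
        max_large=max_set_size,
    )
    enriched = {
        ds.disease_id: t for ds, t in zip(disease_sets, targets) if t is not None
    }
    affinity = true_affinity_matrix(disease_sets, assignment, family)
    freq = make_literature_freq(
        affinity, noise_sd=noise_sd, dropout=dropout, seed=int(rng.integers(2**31))
    )
    params = dict(
        n_modules=n_modules,
        module_size=module_size,
        p_in=p_in,
        p_out=p_out,
        enriched_fraction=enriched_fraction,
        purity=purity,
        noise_sd=noise_sd,
        dropout=dropout,
        bin_mix=list(bin_mix),
    )
    return SyntheticWorld(
        network=net,
        module_assignment=assignment,
        catalog=catalog,
        cytokine_family=family,
        disease_sets=disease_sets,
        enriched=enriched,
        true_affinity=affinity,
        literature_freq=freq,
        seed=seed,
        params=params,
    )
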