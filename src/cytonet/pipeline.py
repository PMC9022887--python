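"""End-to-end orchestration with a config and a hashed run manifest.

``run_all`` executes the stages in order — read/filter inputs, embed the
high-confidence network, score, build profiles and Immune Scores, validate
against literature frequencies, and build/partition disease subnetworks —
writing every intermediate as a plain TSV under the output directory and a
JSON manifest recording the full configuration and the SHA-256 of every
output file.  A rerun with the same config and seeds reproduces identical
hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import (
    CytokineCatalog,
    cluster_cytokines,
    count_validated,
    embed_network,
    filter_high_confidence,
    naas_normalize,
    raw_profiles,
    read_catalog,
    read_disease_sets,
    read_edge_list,
    read_frequency_table,
    select_universe,
    validate_profiles,
)
from .embedding import EmbeddedNetwork, TrainParams, WalkParams
from .errors import CytonetError, InputFormatError
from .profiles import immune_scores, profiles_frame
from .subnetwork import (
    WELL,
    build_subnetwork,
    cytokine_recall,
    fiedler_partition,
    icd,
    partition_summary,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All paths and hyperparameters of one pipeline run.

    Defaults follow the published procedure wherever it states a value:
    confidence cutoff 800, walk length 30, 10 walks per node, window 10,
    64 dimensions, min_count 1, Association Score cutoff 0.8 for
    subnetworks, alpha 0.05 with Bonferroni correction.
    """

    edges_path: str = ""
    diseases_path: str = ""
    catalog_path: str = ""
    frequency_path: str = ""
    out_dir: str = "cytonet_run"
    confidence_cutoff: int = 800
    dim: int = 64
    walk_length: int = 30
    num_walks: int = 10
    window: int = 10
    p: float = 1.0
    q: float = 1.0
    epochs: int = 5
    score_cutoff: float = 0.8
    cluster_k: int = 6
    alpha: float = 0.05
    validation_mode: str = "asymptotic"
    n_perm: int = 100_000
    naas_mode: str = "per-cytokine"
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the run manifest (also written to disk).

    A stage failure aborts with the stage name; outputs of completed stages
    are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "outputs": {}}
    stage = "netio"
    try:
        t0 = time.time()
        for name, p in [
            ("edges", config.edges_path),
            ("diseases", config.diseases_path),
            ("catalog", config.catalog_path),
        ]:
            if not p or not Path(p).exists():
                raise InputFormatError(f"{name} file not found: {p!r}")
        net = read_edge_list(config.edges_path)
        high = filter_high_confidence(net, config.confidence_cutoff)
        universe = select_universe(high)
        catalog = read_catalog(config.catalog_path)
        diseases = read_disease_sets(config.diseases_path, universe)
        logger.info(
            "netio: %d genes, %d edges total; %d high-confidence edges, universe %d; "
            "%d diseases, %d cytokines",
            net.n_genes, net.n_edges, high.n_edges, len(universe), len(diseases),
            catalog.n_cytokines,
        )
        manifest["stages"][stage] = {
            "n_genes": net.n_genes,
            "n_edges": net.n_edges,
            "n_high_conf_edges": high.n_edges,
            "universe": len(universe),
            "n_diseases": len(diseases),
            "seconds": round(time.time() - t0, 2),
        }

        stage = "embedding"
        t0 = time.time()
        emb = embed_network(
            high,
            WalkParams(
                num_walks=config.num_walks,
                walk_length=config.walk_length,
                p=config.p,
                q=config.q,
                seed=config.seed,
            ),
            TrainParams(
                dim=config.dim, window=config.window, epochs=config.epochs, seed=config.seed
            ),
        )
        emb.save(out / "embedding")
        manifest["stages"][stage] = {
            "n_embedded": len(emb.genes),
            "seconds": round(time.time() - t0, 2),
        }

        stage = "profiles"
        t0 = time.time()
        rps = raw_profiles(emb, diseases, catalog)
        profs = naas_normalize(rps, mode=config.naas_mode)  # type: ignore[arg-type]
        pframe = profiles_frame(profs)
        pframe.to_csv(out / "naas.tsv", sep="\t")
        iscores = pd.DataFrame(
            [{"disease_id": s.disease_id, **s.scores} for s in
             (immune_scores(p, catalog) for p in profs)]
        )
        iscores.to_csv(out / "immune_scores.tsv", sep="\t", index=False)
        clustering = cluster_cytokines(
            emb, catalog, universe, k=min(config.cluster_k, catalog.n_cytokines)
        )
        pd.Series(clustering.labels, name="cluster").rename_axis("cytokine").to_csv(
            out / "cytokine_clusters.tsv", sep="\t"
        )
        (out / "cytokine_dendrogram.nwk").write_text(clustering.to_newick() + "\n")
        manifest["stages"][stage] = {
            "n_profiles": len(profs),
            "k": clustering.k,
            "seconds": round(time.time() - t0, 2),
        }

        stage = "validation"
        t0 = time.time()
        n_validated = None
        if config.frequency_path and Path(config.frequency_path).exists():
            freq = read_frequency_table(config.frequency_path)
            results, cutoff = validate_profiles(
                profs,
                freq,
                mode=config.validation_mode,  # type: ignore[arg-type]
                n_perm=config.n_perm,
                seed=config.seed,
                alpha=config.alpha,
            )
            vframe = pd.DataFrame(
                [
                    {
                        "disease_id": r.disease_id,
                        "rho": r.rho,
                        "p_value": r.p_value,
                        "n": r.n_cytokines_compared,
                    }
                    for r in results
                ]
            )
            vframe.to_csv(out / "validation.tsv", sep="\t", index=False)
            n_validated = count_validated(results, cutoff)
            logger.info("validated %d of %d diseases at p < %.2g", n_validated, len(results), cutoff)
            manifest["stages"][stage] = {
                "n_tested": len(results),
                "cutoff": cutoff,
                "n_validated": n_validated,
                "seconds": round(time.time() - t0, 2),
            }

        stage = "subnetwork"
        t0 = time.time()
        rows = []
        part_entries = []
        for ds in diseases:
            sub = build_subnetwork(emb, ds, catalog, cutoff=config.score_cutoff)
            rec = cytokine_recall(ds, sub, catalog)
            rows.append(
                {
                    "disease_id": ds.disease_id,
                    "Np": sub.np_,
                    "Ni": sub.ni,
                    "n_edges": len(sub.edges),
                    "icd": icd(sub),
                    "recall": rec.recall if rec.recall is not None else float("nan"),
                }
            )
            if sub.np_ + sub.ni >= 2:
                part = fiedler_partition(sub)
                part_entries.append((ds, sub, part))
                nxg = sub.to_networkx()
                import networkx as nx

                nx.write_graphml(nxg, out / f"subnetwork_{ds.disease_id}.graphml")
        pd.DataFrame(rows).to_csv(out / "subnetworks.tsv", sep="\t", index=False)
        if part_entries:
            partition_summary(part_entries).to_csv(out / "partitions.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_subnetworks": len(rows),
            "n_partitioned": len(part_entries),
            "seconds": round(time.time() - t0, 2),
        }
    except CytonetError:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.error("pipeline aborted at stage %r", stage)
        raise

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def demo(out_dir, seed: int = 0, **world_kwargs) -> dict:
    """Generate a synthetic world and run the full pipeline on it."""
    from .synthetic import make_world

    out = Path(out_dir)
    world = make_world(seed=seed, **world_kwargs)
    world_dir = out / "world"
    world.write(world_dir)
    config = RunConfig(
        edges_path=str(world_dir / "edges.tsv"),
        diseases_path=str(world_dir / "diseases.tsv"),
        catalog_path=str(world_dir / "catalog.tsv"),
        frequency_path=str(world_dir / "literature_freq.tsv"),
        out_dir=str(out / "run"),
        cluster_k=4,
        seed=seed,
    )
    return run_all(config)
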