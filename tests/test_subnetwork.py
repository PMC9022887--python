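import itertools

import numpy as np
import pytest

from cytonet.embedding import EmbeddedNetwork
from cytonet.errors import InvalidParameterError
from cytonet.netio import CytokineCatalog, DiseaseGeneSet
from cytonet.subnetwork import (
    ARTICULATION,
    POOR,
    WELL,
    DiseaseSubnetwork,
    build_subnetwork,
    cytokine_recall,
    fiedler_partition,
    icd,
    partition_summary,
    retained_percent,
)


def _embedding_with_pair_scores(genes, high_pairs, dim=8):
    """Embedding where listed pairs score ~0.95 and all others ~<0.5.

    Genes sharing a 'group' axis get high mutual cosine; groups are the
    connected components of high_pairs.
    """
    # union-find over high_pairs to place genes on shared axes
    parent = {g: g for g in genes}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for a, b in high_pairs:
        parent[find(a)] = find(b)
    roots = sorted({find(g) for g in genes})
    axis = {r: i for i, r in enumerate(roots)}
    rng = np.random.default_rng(0)
    m = np.zeros((len(genes), max(dim, len(roots) + 1)))
    for i, g in enumerate(genes):
        m[i, axis[find(g)]] = 1.0
        m[i, -1] = 0.15 * rng.random()  # break exact ties
    return EmbeddedNetwork(genes=tuple(genes), matrix=m)


CAT = CytokineCatalog(
    cytokines=("c1", "c2", "c3"),
    category={"c1": "inflammation", "c2": "chemokine", "c3": "other"},
    receptors=frozenset({"r1"}),
)


class TestBuildSubnetwork:
    def test_no_scores_above_cutoff_gives_empty(self):
        genes = ["g1", "g2", "c1", "c2", "c3"]
        emb = _embedding_with_pair_scores(genes, [])  # all cross scores low
        sub = build_subnetwork(emb, DiseaseGeneSet("d", frozenset({"g1", "g2"})), CAT)
        assert sub.is_empty() and icd(sub) == 0.0

    def test_construction_rule(self):
        genes = ["g1", "g2", "c1", "c2", "c3"]
        emb = _embedding_with_pair_scores(genes, [("g1", "c1"), ("g2", "c2")])
        sub = build_subnetwork(emb, DiseaseGeneSet("d", frozenset({"g1", "g2"})), CAT)
        assert sub.np_ == 2 and sub.ni == 2 and len(sub.edges) == 2
        assert set(sub.cytokine_nodes) == {"c1", "c2"}

    def test_receptor_labelling(self):
        genes = ["r1", "g2", "c1", "c2", "c3"]
        emb = _embedding_with_pair_scores(genes, [("r1", "c1")])
        sub = build_subnetwork(emb, DiseaseGeneSet("d", frozenset({"r1", "g2"})), CAT)
        assert sub.pathogenesis_label["r1"] == "receptor"

    def test_cytokine_in_disease_set_sits_on_cytokine_side(self):
        genes = ["g1", "c1", "c2", "c3"]
        emb = _embedding_with_pair_scores(genes, [("g1", "c1")])
        sub = build_subnetwork(emb, DiseaseGeneSet("d", frozenset({"g1", "c1"})), CAT)
        assert "c1" not in sub.pathogenesis_label
        assert "c1" in sub.cytokine_nodes

    def test_strictly_above_cutoff(self):
        genes = ["g1", "c1", "c2", "c3"]
        emb = _embedding_with_pair_scores(genes, [("g1", "c1")])
        sub = build_subnetwork(
            emb, DiseaseGeneSet("d", frozenset({"g1", "c2"})), CAT, cutoff=1.0
        )
        assert sub.is_empty()  # cosine never exceeds 1


def _sub(edges, np_=None, ni=None):
    """Literal subnetwork; Np/Ni inferred from edges unless padded."""
    patho = sorted({a for a, _, _ in edges})
    cytos = sorted({c for _, c, _ in edges})
    if np_ is not None:
        patho += [f"pad_p{i}" for i in range(np_ - len(patho))]
    if ni is not None:
        cytos += [f"pad_c{i}" for i in range(ni - len(cytos))]
    return DiseaseSubnetwork(
        disease_id="d",
        pathogenesis_label={g: "disease_specific" for g in patho},
        cytokine_nodes=tuple(cytos),
        edges=tuple(edges),
    )


class TestIcd:
    def test_complete_bipartite_all_ones(self):
        edges = [(f"g{i}", f"c{j}", 1.0) for i in range(2) for j in range(3)]
        assert icd(_sub(edges)) == pytest.approx(1.0, abs=1e-12)

    def test_partial_edges(self):
        sub = _sub([("g1", "c1", 0.9), ("g2", "c2", 0.8)], np_=2, ni=3)
        assert icd(sub) == pytest.approx((0.9 + 0.8) / 6, abs=1e-12)

    def test_empty_zero(self):
        assert icd(_sub([])) == 0.0

    def test_count_mode(self):
        sub = _sub([("g1", "c1", 0.9), ("g2", "c2", 0.85)], np_=2, ni=2)
        assert icd(sub, mode="count") == pytest.approx(0.5)

    def test_relabel_invariance_and_bounds(self):
        rng = np.random.default_rng(1)
        edges = [
            (f"g{i}", f"c{j}", float(w))
            for (i, j), w in zip(
                itertools.product(range(3), range(4)), rng.uniform(0.8, 1.0, 12)
            )
            if rng.random() < 0.7
        ]
        base = icd(_sub(edges))
        relabeled = [(a.replace("g", "x"), c.replace("c", "y"), w) for a, c, w in edges]
        assert icd(_sub(relabeled)) == pytest.approx(base, abs=1e-15)
        assert base <= max(w for *_, w in edges) + 1e-15

    def test_linear_in_uniform_weight_scaling(self):
        edges = [("g1", "c1", 0.9), ("g1", "c2", 0.85), ("g2", "c1", 0.95)]
        scaled = [(a, c, w / 2) for a, c, w in edges]
        assert icd(_sub(scaled)) == pytest.approx(icd(_sub(edges)) / 2, abs=1e-15)


class TestCytokineRecall:
    def test_partial(self):
        ds = DiseaseGeneSet("d", frozenset({"c1", "c2", "g1"}))
        sub = _sub([("g1", "c1", 0.9)])
        r = cytokine_recall(ds, sub, CAT)
        assert (r.recognized, r.known, r.recall) == (1, 2, 0.5)

    def test_empty_subnetwork(self):
        ds = DiseaseGeneSet("d", frozenset({"c1", "g1"}))
        r = cytokine_recall(ds, _sub([]), CAT)
        assert (r.recognized, r.recall) == (0, 0.0)

    def test_all_recognized(self):
        ds = DiseaseGeneSet("d", frozenset({"c1", "c2"}))
        sub = _sub([("g1", "c1", 0.9), ("g1", "c2", 0.9)])
        assert cytokine_recall(ds, sub, CAT).recall == 1.0

    def test_no_known_flagged(self):
        ds = DiseaseGeneSet("d", frozenset({"g1", "g2"}))
        assert cytokine_recall(ds, _sub([]), CAT).recall is None


class TestFiedlerPartition:
    def test_two_node_path_closed_form(self):
        part = fiedler_partition(nodes=["a", "b"], edges=[("a", "b", 1.0)])
        assert part.fiedler_value == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(np.abs(part.fiedler_vector), [1 / np.sqrt(2)] * 2, atol=1e-9)
        assert sorted(part.classes.values()) == [POOR, WELL]

    def test_three_node_path_articulation(self):
        part = fiedler_partition(
            nodes=["a", "m", "b"], edges=[("a", "m", 1.0), ("m", "b", 1.0)]
        )
        assert part.fiedler_value == pytest.approx(1.0, abs=1e-9)
        assert part.classes["m"] == ARTICULATION
        assert {part.classes["a"], part.classes["b"]} == {WELL, POOR}

    def test_two_blocks_weak_bridge_sign_cut_is_min_cut(self):
        """Two 2x2 complete bipartite blocks joined by one edge: the sign cut
        reproduces the brute-force minimum cut."""
        nodes = ["p1", "p2", "c1", "c2", "q1", "q2", "e1", "e2"]
        block1 = [(p, c, 1.0) for p in ("p1", "p2") for c in ("c1", "c2")]
        block2 = [(q, e, 1.0) for q in ("q1", "q2") for e in ("e1", "e2")]
        edges = block1 + block2 + [("p1", "e1", 1.0)]
        part = fiedler_partition(nodes=nodes, edges=edges, articulation_tol=0.0)
        side = {n: part.classes[n] == WELL for n in nodes}
        cut = sum(1 for a, b, _ in edges if side[a] != side[b])
        assert cut == _brute_min_cut(nodes, edges)

    def test_disconnected_components_split_exactly(self):
        nodes = ["a", "b", "x", "y", "z"]
        edges = [("a", "b", 1.0), ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0)]
        part = fiedler_partition(nodes=nodes, edges=edges)
        assert part.fiedler_value == 0.0
        cls_ab = {part.classes["a"], part.classes["b"]}
        cls_xyz = {part.classes[n] for n in ("x", "y", "z")}
        assert len(cls_ab) == 1 and len(cls_xyz) == 1 and cls_ab != cls_xyz
        # orientation: the triangle (larger total degree) is well-connected
        assert cls_xyz == {WELL}

    def test_orientation_deterministic_under_sign_flip(self):
        nodes = ["a", "b", "c", "d"]
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0), ("b", "d", 1.0)]
        parts = [fiedler_partition(nodes=nodes, edges=edges) for _ in range(3)]
        assert all(p.classes == parts[0].classes for p in parts)

    def test_rejects_single_node(self):
        with pytest.raises(InvalidParameterError):
            fiedler_partition(nodes=["a"], edges=[])

    def test_key_genes_from_well_connected(self):
        nodes = ["p1", "p2", "c1", "c2", "q1", "e1"]
        edges = [(p, c, 1.0) for p in ("p1", "p2") for c in ("c1", "c2")]
        edges += [("q1", "e1", 1.0), ("p1", "e1", 1.0)]
        part = fiedler_partition(
            nodes=nodes, edges=edges, pathogenesis=["p1", "p2", "q1"], articulation_tol=0.0
        )
        assert "q1" not in part.key_genes
        assert {"p1", "p2"} <= set(part.key_genes)


def _brute_min_cut(nodes, edges):
    n = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    best = np.inf
    for mask in range(1, 2 ** (n - 1)):
        side = [(mask >> i) & 1 for i in range(n - 1)] + [0]
        cut = sum(1 for a, b, _ in edges if side[idx[a]] != side[idx[b]])
        best = min(best, cut)
    return best


class TestPlantedCliqueRecovery:
    def test_key_genes_recover_planted_clique(self):
        """A dense gene-cytokine clique plus a weakly bridged peripheral
        group: the well-connected class recovers >= 90% of the clique's
        pathogenesis genes and excludes the periphery."""
        clique_p = [f"p{i}" for i in range(8)]
        clique_c = [f"c{i}" for i in range(6)]
        periph = [f"z{i}" for i in range(5)]
        edges = [(p, c, 1.0) for p in clique_p for c in clique_c]
        # periphery: its own cytokine hub, joined to the clique by one edge
        edges += [(z, "e0", 1.0) for z in periph]
        edges += [("p0", "e0", 1.0)]
        part = fiedler_partition(
            nodes=clique_p + periph + clique_c + ["e0"],
            edges=edges,
            pathogenesis=clique_p + periph,
        )
        recovered = set(part.key_genes) & set(clique_p)
        assert len(recovered) / len(clique_p) >= 0.9
        assert not (set(part.key_genes) & set(periph))


class TestPartitionSummary:
    @pytest.mark.parametrize("kept,total,expected", [(36, 1340, 2.7), (0, 10, 0.0), (10, 10, 100.0)])
    def test_retained_percent(self, kept, total, expected):
        assert retained_percent(kept, total) == expected

    def test_summary_frame(self):
        ds = DiseaseGeneSet("d", frozenset({"g1", "g2", "r1"}))
        sub = DiseaseSubnetwork(
            disease_id="d",
            pathogenesis_label={"g1": "disease_specific", "r1": "receptor"},
            cytokine_nodes=("c1",),
            edges=(("g1", "c1", 0.9), ("r1", "c1", 0.9)),
        )
        part = fiedler_partition(sub, articulation_tol=0.0)
        df = partition_summary([(ds, sub, part)])
        row = df.iloc[0]
        assert row["input_genes"] == 3
        assert row["receptors_in_module"] + row["disease_genes_in_module"] <= 2
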