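"""Target prioritization funnel and cascade tracing."""
from __future__ import annotations

import pandas as pd
import pytest

from mirtox import targets
from mirtox.containers import AnnotationCatalog, InteractionGraph, TargetNetwork
from mirtox.targets import PrioritizedTarget


class TestSelectValidated:
    def test_validated_only_with_provenance(self, tiny_network):
        out = targets.select_validated_targets(["m1", "m2"], tiny_network)
        got = {r.gene: r.supporting_mirnas for r in out.itertuples()}
        # g2 is a predicted edge and must not appear
        assert got == {"g1": ["m1"], "g3": ["m2"], "g4": ["m2"]}

    def test_shared_target_lists_both_mirnas(self, tiny_network):
        out = targets.select_validated_targets(["m1", "m3"], tiny_network)
        got = {r.gene: r.supporting_mirnas for r in out.itertuples()}
        assert got["g1"] == ["m1", "m3"]

    def test_set_algebra_oracle(self, tiny_network):
        # result gene set == union of the per-miRNA validated target sets
        sig = ["m1", "m2", "m3"]
        out = targets.select_validated_targets(sig, tiny_network)
        expected = tiny_network.targets_of_set(sig, evidence="validated")
        assert set(out["gene"]) == expected

    def test_no_hits_gives_empty_table(self, tiny_network):
        out = targets.select_validated_targets(["m99"], tiny_network)
        assert out.empty
        assert list(out.columns) == ["gene", "supporting_mirnas"]


class TestFilterNeuroTargets:
    def _table(self, genes):
        return pd.DataFrame(
            {"gene": genes, "supporting_mirnas": [["m1"]] * len(genes)}
        )

    def test_each_drop_step(self, tiny_catalog):
        survivors, audit = targets.filter_neuro_targets(
            self._table(["g1", "g2", "g3", "g9"]), tiny_catalog
        )
        assert [t.gene for t in survivors] == ["g1"]
        outcome = audit.set_index("gene")
        assert outcome.loc["g9", "reason"] == "no neurological annotation"
        assert outcome.loc["g3", "reason"] == "no biomarker or pathway relationship"
        assert outcome.loc["g2", "reason"] == "associated with a single condition only"
        assert outcome.loc["g1", "outcome"] == "kept"

    def test_survivor_counts(self, tiny_catalog):
        survivors, _ = targets.filter_neuro_targets(self._table(["g1"]), tiny_catalog)
        t = survivors[0]
        assert (t.n_biomarker_terms, t.n_pathway_terms) == (1, 1)

    def test_two_biomarkers_no_pathway_survives(self):
        catalog = AnnotationCatalog(
            pd.DataFrame(
                [
                    ("gx", "parkinsons", "disease_biomarker"),
                    ("gx", "huntingtons", "disease_biomarker"),
                ],
                columns=["gene", "term", "category"],
            )
        )
        survivors, _ = targets.filter_neuro_targets(self._table(["gx"]), catalog)
        assert [t.gene for t in survivors] == ["gx"]

    def test_brute_force_oracle(self, tiny_catalog):
        # independent re-derivation of the three rules from the raw table
        genes = ["g1", "g2", "g3", "g9"]
        survivors, _ = targets.filter_neuro_targets(self._table(genes), tiny_catalog)
        raw = tiny_catalog.table
        expected = []
        for g in genes:
            sub = raw[raw["gene"] == g]
            if sub.empty:
                continue
            bp = sub[sub["category"].isin(["disease_biomarker", "canonical_pathway"])]
            if bp.empty or bp["term"].nunique() == 1:
                continue
            expected.append(g)
        assert [t.gene for t in survivors] == expected


class TestPredictDirection:
    def _target(self, fcs):
        return PrioritizedTarget(
            gene="g",
            supporting_mirnas=sorted(fcs),
            mirna_log2fc=dict(fcs),
        )

    def test_single_down_mirna_predicts_up(self):
        t = self._target({"m1": -2.0})
        assert targets.predict_direction(t) == "up"
        assert t.predicted_direction == "up"

    def test_single_up_mirna_predicts_down(self):
        assert targets.predict_direction(self._target({"m1": 1.5})) == "down"

    def test_equal_opposite_is_ambiguous(self):
        assert (
            targets.predict_direction(self._target({"m1": 2.0, "m2": -2.0}))
            == "ambiguous"
        )

    def test_magnitude_weighted_vote(self):
        # down-votes |−2| + |−1| = 3 beat the up-vote |0.5|
        t = self._target({"m1": -2.0, "m2": -1.0, "m3": 0.5})
        assert targets.predict_direction(t) == "up"

    def test_negating_all_fcs_flips_direction(self):
        fcs = {"m1": -1.7, "m2": 0.4, "m3": -0.2}
        fwd = targets.predict_direction(self._target(fcs))
        rev = targets.predict_direction(
            self._target({m: -v for m, v in fcs.items()})
        )
        assert {fwd, rev} == {"up", "down"}

    def test_mirna_without_fc_is_skipped(self):
        t = PrioritizedTarget(
            gene="g", supporting_mirnas=["m1", "m2"], mirna_log2fc={"m1": -1.0}
        )
        assert targets.predict_direction(t) == "up"


class TestPrioritizeTargets:
    def test_end_to_end(self, tiny_network, tiny_catalog):
        survivors, audit = targets.prioritize_targets(
            ["m1", "m2", "m3"],
            {"m1": -2.0, "m2": 1.0, "m3": -0.5},
            tiny_network,
            tiny_catalog,
        )
        assert [t.gene for t in survivors] == ["g1"]
        t = survivors[0]
        assert t.supporting_mirnas == ["m1", "m3"]
        assert t.predicted_direction == "up"  # both repressors went down
        assert set(audit["gene"]) == {"g1", "g3", "g4"}

    def test_funnel_monotone_in_mirna_set(self, tiny_network, tiny_catalog):
        fcs = {"m1": -2.0, "m2": 1.0, "m3": -0.5}
        small, _ = targets.prioritize_targets(["m1"], fcs, tiny_network, tiny_catalog)
        large, _ = targets.prioritize_targets(
            ["m1", "m2", "m3"], fcs, tiny_network, tiny_catalog
        )
        assert {t.gene for t in small} <= {t.gene for t in large}

    def test_targets_table_columns(self, tiny_network, tiny_catalog):
        survivors, _ = targets.prioritize_targets(
            ["m1", "m3"], {"m1": -2.0, "m3": -0.5}, tiny_network, tiny_catalog
        )
        table = targets.targets_table(survivors)
        assert list(table.columns) == [
            "gene",
            "supporting_mirnas",
            "n_biomarker_terms",
            "n_pathway_terms",
            "predicted_direction",
            "rationale",
        ]
        assert table["supporting_mirnas"].iloc[0] == "m1;m3"


def brute_force_paths(graph: InteractionGraph, sources, sinks, max_len):
    g = graph.graph
    found = []

    def dfs(path):
        node = path[-1]
        if len(path) > 1 and node in sinks:
            found.append(list(path))
        if len(path) - 1 >= max_len:
            return
        for nxt in g.successors(node):
            if nxt not in path:
                path.append(nxt)
                dfs(path)
                path.pop()

    for s in sorted(sources):
        dfs([s])
    found.sort(key=tuple)
    return found


class TestTraceCascades:
    def test_single_edge(self, line_graph):
        assert targets.trace_cascades(line_graph, ["a"], ["b"]) == [["a", "b"]]

    def test_two_routes_to_c(self, line_graph):
        paths = targets.trace_cascades(line_graph, ["a"], ["c"])
        assert paths == [["a", "b", "c"], ["a", "c"]]

    def test_max_len_respected(self, line_graph):
        paths = targets.trace_cascades(line_graph, ["a"], ["d"], max_len=2)
        assert paths == [["a", "c", "d"]]  # a-b-c-d needs 3 edges

    def test_disconnected_gives_empty(self):
        g = InteractionGraph.from_edges(
            [("a", "activating", "b"), ("c", "activating", "d")]
        )
        assert targets.trace_cascades(g, ["a"], ["d"]) == []

    def test_missing_seed_lists_ids(self, line_graph):
        with pytest.raises(KeyError, match="zz"):
            targets.trace_cascades(line_graph, ["a", "zz"], ["d"])

    def test_no_repeated_nodes(self, line_graph):
        for path in targets.trace_cascades(line_graph, ["a"], ["c", "d"]):
            assert len(path) == len(set(path))

    def test_matches_brute_force_on_random_graphs(self):
        import numpy as np

        rng = np.random.default_rng(11)
        nodes = [f"n{i}" for i in range(10)]
        for trial in range(5):
            edges = []
            for u in nodes:
                for v in nodes:
                    if u != v and rng.random() < 0.18:
                        edges.append((u, "activating", v))
            g = InteractionGraph.from_edges(edges)
            srcs = [n for n in nodes[:3] if n in g.graph]
            snks = set(n for n in nodes[7:] if n in g.graph)
            if not srcs or not snks:
                continue
            got = targets.trace_cascades(g, srcs, snks, max_len=3)
            assert got == brute_force_paths(g, srcs, snks, 3)


class TestMergeCascades:
    def test_shared_edges_deduplicated(self, line_graph):
        paths = [["a", "b", "c"], ["a", "c"], ["a", "c", "d"]]
        edges, node_table = targets.merge_cascades(paths, line_graph)
        assert len(edges) == 4
        # edge union oracle: every consecutive pair appears exactly once
        expected = {
            ("a", "activating", "b"),
            ("b", "inhibiting", "c"),
            ("a", "unknown", "c"),
            ("c", "activating", "d"),
        }
        assert set(map(tuple, edges.to_numpy())) == expected
        assert list(node_table["node"]) == ["a", "b", "c", "d"]

    def test_empty_paths(self, line_graph):
        edges, node_table = targets.merge_cascades([], line_graph)
        assert edges.empty and node_table.empty

    def test_annotations_attached(self, line_graph):
        catalog = AnnotationCatalog(
            pd.DataFrame(
                [("b", "parkinsons", "disease_biomarker")],
                columns=["gene", "term", "category"],
            )
        )
        edges, node_table = targets.merge_cascades(
            [["a", "b", "c"]],
            line_graph,
            catalog=catalog,
            notable_mirnas_by_gene={"c": ["m2", "m1"]},
        )
        row = node_table.set_index("node")
        assert row.loc["b", "categories"] == "disease_biomarker"
        assert row.loc["c", "notable_mirnas"] == "m1;m2"
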