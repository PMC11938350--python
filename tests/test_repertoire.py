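"""Clone grouping, node collapse, classification, lineage trees, scoring."""

import numpy as np
import pandas as pd
import pytest

from gcplasma import SimConfig, run, sample_cells
from gcplasma.repertoire import (
    build_lineage_tree,
    build_nodes,
    classify_node,
    group_clones,
    has_affinity_mutation,
    mutation_load,
    summarize,
    to_newick,
)
from gcplasma.tables import SchemaError, split_mutations

from conftest import make_cell_row, make_table


class TestGroupClones:
    def test_single_cell(self):
        t = make_table([make_cell_row(0)])
        clones = group_clones(t)
        assert len(clones) == 1 and clones[0].size == 1

    def test_junction_distinguishes_clones(self):
        t = make_table(
            [
                make_cell_row(0, junction="AAATTTGGG"),
                make_cell_row(1, junction="AAATTTGGC"),
            ]
        )
        assert len(group_clones(t)) == 2

    def test_missing_columns_named(self):
        with pytest.raises(SchemaError, match="junction"):
            group_clones(pd.DataFrame({"v_call": ["IGHV1-72"]}))

    def test_partition_covers_table(self):
        t = make_table(
            [make_cell_row(i, clone_id=f"c{i % 3}", junction=f"AAATTTGG{'ACGT'[i % 3]}")
             for i in range(12)]
        )
        clones = group_clones(t)
        assert sum(c.size for c in clones) == len(t)

    def test_recovers_simulator_founder_partition(self, tiny_config):
        state = run(tiny_config)
        table = sample_cells(state)
        clones = group_clones(table)
        # clone partition must equal the founder-id partition exactly
        recovered = {frozenset(c.table["cell_id"]) for c in clones}
        truth = {
            frozenset(sub["cell_id"])
            for _, sub in table.groupby("clone_id")
        }
        assert recovered == truth


class TestBuildNodes:
    def test_unmutated_clone_is_one_node(self):
        t = make_table([make_cell_row(i) for i in range(3)])
        nodes = build_nodes(group_clones(t)[0])
        assert len(nodes) == 1 and nodes[0].size == 3

    def test_signature_split(self):
        t = make_table(
            [
                make_cell_row(0),
                make_cell_row(1, mutations_heavy="W33L"),
                make_cell_row(2, mutations_heavy="W33L"),
            ]
        )
        nodes = build_nodes(group_clones(t)[0])
        assert sorted(n.size for n in nodes) == [1, 2]

    def test_matches_pairwise_equality_oracle(self, tiny_config):
        state = run(tiny_config)
        table = sample_cells(state)
        for clone in group_clones(table):
            nodes = build_nodes(clone)
            # O(n^2) oracle: same node iff identical mutation signatures
            rows = clone.table.reset_index(drop=True)
            sig = [
                (split_mutations(r["mutations_heavy"]), split_mutations(r["mutations_light"]))
                for _, r in rows.iterrows()
            ]
            node_of = {}
            for node in nodes:
                for cid in node.cell_ids:
                    node_of[cid] = node.node_id
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    same = sig[i] == sig[j]
                    ci, cj = rows.loc[i, "cell_id"], rows.loc[j, "cell_id"]
                    assert (node_of[ci] == node_of[cj]) == same
            assert sum(n.size for n in nodes) == clone.size


class TestClassifyNode:
    @pytest.mark.parametrize(
        "comps,expected",
        [
            (("LZ", "DZ"), "GC_only"),
            (("PC",), "PC_only"),
            (("LZ", "PC"), "mixed"),
            (("prePC",), "GC_only"),  # prePCs count as GC-phenotype cells
        ],
    )
    def test_classes(self, comps, expected):
        t = make_table([make_cell_row(i, compartment=c) for i, c in enumerate(comps)])
        node = build_nodes(group_clones(t)[0])[0]
        assert classify_node(node) == expected

    def test_prepc_exclusion_flag(self):
        t = make_table([make_cell_row(0, compartment="prePC")])
        node = build_nodes(group_clones(t)[0])[0]
        with pytest.raises(ValueError):
            classify_node(node, include_prepc_as_gc=False)

    def test_unknown_compartment(self):
        t = make_table([make_cell_row(0)])
        node = build_nodes(group_clones(t)[0])[0]
        node.compartments = ("plasmablast",)
        with pytest.raises(ValueError):
            classify_node(node)


class TestLineageTree:
    def _tree_for(self, mutation_sets):
        rows = [
            make_cell_row(i, mutations_heavy=";".join(sorted(m)))
            for i, m in enumerate(mutation_sets)
        ]
        clone = group_clones(make_table(rows))[0]
        return build_lineage_tree(clone)

    def test_chain(self):
        tree = self._tree_for([set(), {"A"}, {"A", "B"}])
        nodes = {tuple(sorted(n.signature_heavy)): nid for nid, n in tree.nodes.items()}
        root_node = nodes[()]
        a = nodes[("A",)]
        ab = nodes[("A", "B")]
        assert tree.parent[root_node] is None
        assert tree.parent[a] == root_node and tree.edge_length[a] == 1
        assert tree.parent[ab] == a and tree.edge_length[ab] == 1

    def test_no_subset_relation_both_root_children(self):
        tree = self._tree_for([{"A"}, {"B"}])
        assert all(p is None for p in tree.parent.values())
        assert all(length == 1 for length in tree.edge_length.values())

    def test_edges_equal_nodes(self):
        tree = self._tree_for([set(), {"A"}, {"B"}, {"A", "C"}])
        assert len(tree.edge_length) == len(tree.nodes)

    def test_parent_signatures_subset_of_true_ancestry(self, tiny_config):
        """Reconstructed parent signatures must be contained in the child's,
        consistent with mutation sets only growing along simulated lineages."""
        state = run(tiny_config)
        table = sample_cells(state)
        for clone in group_clones(table):
            tree = build_lineage_tree(clone)
            for nid, pid in tree.parent.items():
                if pid is not None:
                    assert tree.nodes[pid].signature < tree.nodes[nid].signature
                    assert tree.edge_length[nid] >= 1

    def test_newick_renders(self):
        tree = self._tree_for([set(), {"A"}])
        nwk = to_newick(tree)
        assert nwk.endswith("germline;") and "&size=1" in nwk


class TestScoring:
    def test_hotspot_requires_analog_germline(self):
        hot = make_cell_row(0, mutations_heavy="W33L")
        cold = make_cell_row(1, v_call="IGHV9-3", mutations_heavy="W33L")
        neutral = make_cell_row(2, mutations_heavy="n17u3")
        t = make_table([hot, cold, neutral])
        flags = [has_affinity_mutation(r) for _, r in t.iterrows()]
        assert flags == [True, False, False]

    def test_mutation_load(self):
        r = pd.Series({"mutations_heavy": "a;b", "mutations_light": "c"})
        assert mutation_load(r) == 3
        r0 = pd.Series({"mutations_heavy": "", "mutations_light": ""})
        assert mutation_load(r0) == 0


class TestSummarize:
    def test_all_hotspot_gives_fraction_one(self):
        rows = [
            make_cell_row(0, compartment="LZ", mutations_heavy="W33L"),
            make_cell_row(1, compartment="PC", mutations_heavy="W33L"),
        ]
        s = summarize(make_table(rows))
        m = s.per_mouse.iloc[0]
        assert m["gc_hotspot_fraction"] == 1.0
        assert m["pc_hotspot_fraction"] == 1.0

    def test_hand_worked_two_mouse_fixture(self):
        rows = [
            # mouse m0: 2 GC (1 hot), 1 PC (hot)
            make_cell_row(0, mouse_id="m0", compartment="LZ", mutations_heavy="W33L"),
            make_cell_row(1, mouse_id="m0", compartment="DZ"),
            make_cell_row(2, mouse_id="m0", compartment="PC", mutations_heavy="K59R"),
            # mouse m1: 1 GC (cold germline), 2 PC (0 hot)
            make_cell_row(3, mouse_id="m1", compartment="LZ", v_call="IGHV9-3"),
            make_cell_row(4, mouse_id="m1", compartment="PC"),
            make_cell_row(5, mouse_id="m1", compartment="PC", mutations_light="n5u1"),
        ]
        s = summarize(make_table(rows))
        per = s.per_mouse.set_index("mouse_id")
        assert per.loc["m0", "gc_hotspot_fraction"] == pytest.approx(0.5)
        assert per.loc["m0", "pc_hotspot_fraction"] == pytest.approx(1.0)
        assert per.loc["m1", "pc_hotspot_fraction"] == pytest.approx(0.0)
        assert per.loc["m1", "gc_high_affinity_germline_fraction"] == 0.0
        assert s.pooled.loc["pc_hotspot_fraction", "mean"] == pytest.approx(0.5)

    def test_missing_compartment_reported_as_nan(self):
        rows = [make_cell_row(0, compartment="LZ")]
        m = summarize(make_table(rows)).per_mouse.iloc[0]
        assert np.isnan(m["pc_hotspot_fraction"])

    def test_row_order_invariance(self, tiny_config):
        state = run(tiny_config)
        table = sample_cells(state)
        a = summarize(table).per_mouse
        b = summarize(table.sample(frac=1.0, random_state=3)).per_mouse
        pd.testing.assert_frame_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(make_table([]))
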