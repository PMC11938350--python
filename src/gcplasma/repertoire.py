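"""Clonal repertoire analysis: clones, identical-sequence nodes, node-type
classification, germline-rooted lineage trees and mutation scoring.

A *clone* is the set of cells sharing both germline V calls and both
junction strings (exact paired-junction identity).  Within a clone, a
*node* is the set of cells carrying the identical heavy+light mutation
signature -- "cells with identical sequences".  Nodes are classified as
GC-only, PC-only or mixed by the compartments of their members; mixed
nodes containing both cell types are the signature of shared GC/PC
clonal expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import HIGH_AFFINITY_GERMLINE, HOTSPOT_MUTATIONS
from .tables import SchemaError, split_mutations

_CLONE_KEY = ("v_call", "v_call_light", "junction", "junction_light")

#: compartment -> analysis cell type (prePCs are GC-phenotype cells)
GC_CLASS = ("LZ", "DZ")
PC_CLASS = ("PC",)


@dataclass
class Clone:
    clone_id: str
    v_call: str
    v_call_light: str
    junction: str
    junction_light: str
    table: pd.DataFrame

    @property
    def size(self) -> int:
        return len(self.table)


@dataclass
class Node:
    node_id: str
    clone_id: str
    cell_ids: tuple
    signature_heavy: frozenset[str]
    signature_light: frozenset[str]
    compartments: tuple[str, ...]
    composition: str = ""

    @property
    def size(self) -> int:
        return len(self.cell_ids)

    @property
    def signature(self) -> frozenset[str]:
        """Heavy+light mutation signature as one chain-tagged set."""
        return frozenset(f"H:{m}" for m in self.signature_heavy) | frozenset(
            f"L:{m}" for m in self.signature_light
        )


@dataclass
class LineageTree:
    """Germline-rooted minimum-mutation linking of a clone's nodes.

    ``parent[node_id]`` is the parent node id, or ``None`` for children of
    the (virtual) unmutated germline root.  Edge length is the size of the
    mutation-set difference to the parent.
    """

    clone_id: str
    nodes: dict[str, Node]
    parent: dict[str, str | None]
    edge_length: dict[str, int]

    def children(self, node_id: str | None) -> list[str]:
        return sorted(k for k, v in self.parent.items() if v == node_id)


def group_clones(table: pd.DataFrame) -> list[Clone]:
    """Partition cells into clones by exact paired V-call + junction identity."""
    missing = [c for c in _CLONE_KEY if c not in table.columns]
    if missing:
        raise SchemaError(f"clone grouping needs column(s): {', '.join(missing)}")
    clones = []
    if len(table) == 0:
        return clones
    for i, (key, sub) in enumerate(sorted(table.groupby(list(_CLONE_KEY)),
                                          key=lambda kv: kv[0])):
        vh, vl, jh, jl = key
        clones.append(Clone(f"c{i}", vh, vl, jh, jl, sub))
    return clones


def _signature_of_row(row: pd.Series) -> tuple[frozenset[str], frozenset[str]]:
    return split_mutations(row["mutations_heavy"]), split_mutations(row["mutations_light"])


def build_nodes(clone: Clone) -> list[Node]:
    """Partition a clone's cells by exact heavy+light mutation-set equality."""
    groups: dict[tuple, list] = {}
    for _, row in clone.table.iterrows():
        sh, sl = _signature_of_row(row)
        key = (tuple(sorted(sh)), tuple(sorted(sl)))
        groups.setdefault(key, []).append(row)
    nodes = []
    for i, key in enumerate(sorted(groups)):
        rows = groups[key]
        nodes.append(
            Node(
                node_id=f"{clone.clone_id}.n{i}",
                clone_id=clone.clone_id,
                cell_ids=tuple(r["cell_id"] for r in rows),
                signature_heavy=frozenset(key[0]),
                signature_light=frozenset(key[1]),
                compartments=tuple(r["compartment"] for r in rows),
            )
        )
    return nodes


def classify_node(node: Node, include_prepc_as_gc: bool = True) -> str:
    """GC_only / PC_only / mixed, from the members' compartments."""
    gc_comps = set(GC_CLASS) | ({"prePC"} if include_prepc_as_gc else set())
    kinds = set()
    for comp in node.compartments:
        if comp in gc_comps:
            kinds.add("GC")
        elif comp in PC_CLASS:
            kinds.add("PC")
        else:
            raise ValueError(f"unknown compartment {comp!r} in node {node.node_id}")
    if kinds == {"GC"}:
        return "GC_only"
    if kinds == {"PC"}:
        return "PC_only"
    return "mixed"


def build_lineage_tree(clone: Clone, nodes: list[Node] | None = None) -> LineageTree:
    """Greedy minimum-mutation linking under the no-back-mutation assumption.

    Each node's parent is the node whose signature is a subset of its own
    with maximal size (ties: larger node, then lexicographic node id);
    nodes with no such ancestor hang off the virtual germline root.
    """
    if nodes is None:
        nodes = build_nodes(clone)
    sigs = {n.node_id: n.signature for n in nodes}
    if len(set(sigs.values())) != len(sigs):
        raise RuntimeError(f"clone {clone.clone_id}: duplicate node signatures")
    parent: dict[str, str | None] = {}
    edge: dict[str, int] = {}
    by_id = {n.node_id: n for n in nodes}
    for n in nodes:
        best_rank: tuple | None = None
        best_id: str | None = None
        for m in nodes:
            if m.node_id == n.node_id:
                continue
            sm = sigs[m.node_id]
            if sm < sigs[n.node_id]:  # strict subset
                rank = (len(sm), m.size)
                if (
                    best_rank is None
                    or rank > best_rank
                    or (rank == best_rank and m.node_id < best_id)
                ):
                    best_rank, best_id = rank, m.node_id
        if best_id is None:
            parent[n.node_id] = None
            edge[n.node_id] = len(sigs[n.node_id])
        else:
            parent[n.node_id] = best_id
            edge[n.node_id] = len(sigs[n.node_id]) - len(sigs[best_id])
    return LineageTree(clone.clone_id, by_id, parent, edge)


def to_newick(tree: LineageTree) -> str:
    """Newick with node sizes in comments; the germline root is virtual."""

    def render(node_id: str) -> str:
        kids = tree.children(node_id)
        node = tree.nodes[node_id]
        label = f"{node.node_id}[&size={node.size}]:{tree.edge_length[node_id]}"
        if not kids:
            return label
        return "(" + ",".join(render(k) for k in kids) + ")" + label

    top = tree.children(None)
    inner = ",".join(render(k) for k in top)
    return f"({inner})germline;" if inner else "germline;"


def has_affinity_mutation(
    row: pd.Series,
    hotspot_set: frozenset[str] = frozenset(HOTSPOT_MUTATIONS),
    analog_germline: str = HIGH_AFFINITY_GERMLINE,
) -> bool:
    """True iff the cell uses the high-affinity-capable germline AND carries
    at least one of the designated affinity-enhancing substitutions."""
    if not hotspot_set:
        raise ValueError("hotspot set must be nonempty")
    if row["v_call"] != analog_germline:
        return False
    return bool(split_mutations(row["mutations_heavy"]) & hotspot_set)


def mutation_load(row: pd.Series) -> int:
    """Total VH+VL mutation count of one cell."""
    return len(split_mutations(row["mutations_heavy"])) + len(
        split_mutations(row["mutations_light"])
    )


def _cell_type(comp: str, include_prepc_as_gc: bool = True) -> str | None:
    if comp in GC_CLASS or (include_prepc_as_gc and comp == "prePC"):
        return "GC"
    if comp in PC_CLASS:
        return "PC"
    return None


@dataclass
class RepertoireSummary:
    """Per-replicate repertoire statistics plus the pooled mean +/- SD."""

    per_mouse: pd.DataFrame
    pooled: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.pooled) == 0 and len(self.per_mouse) > 0:
            num = self.per_mouse.drop(columns=["mouse_id"])
            self.pooled = pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})


def summarize(
    table: pd.DataFrame,
    hotspot_set: frozenset[str] = frozenset(HOTSPOT_MUTATIONS),
    include_prepc_as_gc: bool = True,
) -> RepertoireSummary:
    """Figure-style per-mouse repertoire summary.

    Statistics whose denominator is empty for a replicate (e.g. the PC
    hotspot fraction of a PC-free mouse) are reported as missing (NaN),
    never as zero.
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty cell table")
    records = []
    for mouse_id, sub in table.groupby("mouse_id"):
        sub = sub.reset_index(drop=True)
        ct = sub["compartment"].map(lambda c: _cell_type(c, include_prepc_as_gc))
        gc_rows = sub[ct == "GC"]
        pc_rows = sub[ct == "PC"]
        hot = sub.apply(lambda r: has_affinity_mutation(r, hotspot_set), axis=1)
        loads = sub.apply(mutation_load, axis=1)

        clones = group_clones(sub)
        class_counts = {"GC_only": 0, "PC_only": 0, "mixed": 0}
        class_sizes: dict[str, list[int]] = {"GC_only": [], "PC_only": [], "mixed": []}
        class_hot: dict[str, list[bool]] = {"GC_only": [], "PC_only": [], "mixed": []}
        pcs_in_mixed = 0
        for clone in clones:
            for node in build_nodes(clone):
                cls = classify_node(node, include_prepc_as_gc)
                node.composition = cls
                class_counts[cls] += 1
                class_sizes[cls].append(node.size)
                node_hot = bool(
                    node.signature_heavy & hotspot_set
                ) and node.compartments and clone.v_call == HIGH_AFFINITY_GERMLINE
                class_hot[cls].append(node_hot)
                if cls == "mixed":
                    pcs_in_mixed += sum(
                        1 for c in node.compartments if _cell_type(c, include_prepc_as_gc) == "PC"
                    )

        def _frac(series: pd.Series) -> float:
            return float(series.mean()) if len(series) else float("nan")

        records.append(
            {
                "mouse_id": mouse_id,
                "n_cells": len(sub),
                "n_gc": len(gc_rows),
                "n_pc": len(pc_rows),
                "n_clones": len(clones),
                "nodes_gc_only": class_counts["GC_only"],
                "nodes_pc_only": class_counts["PC_only"],
                "nodes_mixed": class_counts["mixed"],
                "mean_size_gc_only": float(np.mean(class_sizes["GC_only"])) if class_sizes["GC_only"] else float("nan"),
                "mean_size_pc_only": float(np.mean(class_sizes["PC_only"])) if class_sizes["PC_only"] else float("nan"),
                "mean_size_mixed": float(np.mean(class_sizes["mixed"])) if class_sizes["mixed"] else float("nan"),
                "frac_nodes_hotspot_gc_only": float(np.mean(class_hot["GC_only"])) if class_hot["GC_only"] else float("nan"),
                "frac_nodes_hotspot_pc_only": float(np.mean(class_hot["PC_only"])) if class_hot["PC_only"] else float("nan"),
                "frac_nodes_hotspot_mixed": float(np.mean(class_hot["mixed"])) if class_hot["mixed"] else float("nan"),
                "gc_hotspot_fraction": _frac(hot[ct == "GC"]),
                "pc_hotspot_fraction": _frac(hot[ct == "PC"]),
                "gc_high_affinity_germline_fraction": _frac(
                    (gc_rows["v_call"] == HIGH_AFFINITY_GERMLINE) if len(gc_rows) else pd.Series(dtype=float)
                ),
                "pc_high_affinity_germline_fraction": _frac(
                    (pc_rows["v_call"] == HIGH_AFFINITY_GERMLINE) if len(pc_rows) else pd.Series(dtype=float)
                ),
                "frac_pcs_in_mixed_nodes": pcs_in_mixed / len(pc_rows) if len(pc_rows) else float("nan"),
                "mean_mutation_load": float(loads.mean()),
                "mean_mutation_load_pc": _frac(loads[ct == "PC"]),
                "mean_mutation_load_gc": _frac(loads[ct == "GC"]),
            }
        )
    return RepertoireSummary(pd.DataFrame.from_records(records))
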