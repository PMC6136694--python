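"""Architecture calls per genome and their distribution on a species tree.

The architecture rule: a genome encoding Spo0A, Spo0F and Spo0B is called a
PHOSPHORELAY; Spo0A with neither intermediate is DIRECT phosphorylation;
Spo0A with exactly one of Spo0F/Spo0B is PARTIAL_RELAY (the intermediate
cases the pathway survey leaves unnamed); no Spo0A is NO_SPO0.

The patchiness of the architecture distribution is quantified with Fitch
small parsimony: the minimum number of state changes required to explain the
leaf labels on a rooted tree.  A count well above one is the quantitative
footprint of multiple independent transitions between architectures.
"""

from __future__ import annotations

from io import StringIO
from typing import Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .model import Architecture, ArchitectureCall, Spo0Inventory


def call_architecture(inv: Spo0Inventory) -> ArchitectureCall:
    """Categorical pathway label from the per-genome inventory (pure function)."""
    has_a = bool(inv.spo0a)
    has_f = inv.spo0f is not None
    has_b = inv.spo0b is not None
    if not has_a:
        label = Architecture.NO_SPO0
        why = "no Spo0A detected"
    elif has_f and has_b:
        label = Architecture.PHOSPHORELAY
        why = "Spo0A with both Spo0F and Spo0B"
    elif has_f or has_b:
        label = Architecture.PARTIAL_RELAY
        why = "Spo0A with only " + ("Spo0F" if has_f else "Spo0B")
    else:
        label = Architecture.DIRECT
        why = "Spo0A without Spo0F or Spo0B"
    return ArchitectureCall(genome_id=inv.genome_id, label=label.value, rationale=why)


# -- Fitch small parsimony ----------------------------------------------

class _Node:
    __slots__ = ("children", "label", "key")

    def __init__(self, children=None, label=None, key=""):
        self.children: list[_Node] = children or []
        self.label: Optional[str] = label
        self.key: str = key  # min leaf name below, for deterministic ordering


def _to_tree(tree: "dendropy.Tree | str") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick")


def _build(node, labels: Mapping[str, str], states: set[str]) -> Optional[_Node]:
    if node.is_leaf():
        name = node.taxon.label if node.taxon else None
        if name is None:
            raise ValueError("tree has an unnamed leaf")
        name = name.replace(" ", "_")
        if name not in labels:
            raise ValueError(f"leaf {name!r} has no architecture label")
        state = labels[name]
        if state not in states:
            return None  # pruned
        return _Node(label=state, key=name)
    kids = [k for k in (_build(c, labels, states) for c in node.child_nodes()) if k]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]  # suppress unifurcation left by pruning
    kids.sort(key=lambda n: n.key)
    # resolve polytomies deterministically: left-fold over sorted children
    while len(kids) > 2:
        merged = _Node(children=[kids[0], kids[1]], key=kids[0].key)
        kids = [merged] + kids[2:]
    return _Node(children=kids, key=kids[0].key)


def fitch_transition_count(
    tree: "dendropy.Tree | str",
    labels: Mapping[str, str],
    states: Optional[Sequence[str]] = None,
) -> int:
    """Minimum number of label changes on the tree under Fitch parsimony.

    ``labels`` maps leaf names (genome ids) to architecture labels; leaves
    whose label is outside ``states`` (default: every label present) are
    pruned before counting.  Deterministic: polytomies are resolved in
    sorted child order.
    """
    dtree = _to_tree(tree)
    state_set = set(states) if states is not None else set(labels.values())
    root = _build(dtree.seed_node, labels, state_set)
    if root is None:
        return 0
    count = 0

    def post(node: _Node) -> set[str]:
        nonlocal count
        if not node.children:
            return {node.label}  # type: ignore[arg-type]
        left = post(node.children[0])
        right = post(node.children[1])
        inter = left & right
        if inter:
            return inter
        count += 1
        return left | right

    post(root)
    return count


# -- reporting -----------------------------------------------------------

REPORT_COLUMNS = [
    "genome_id",
    "orphan_kinase",
    "pas_orphan",
    "spo0f",
    "spo0b",
    "spo0a",
    "architecture",
    "phenotype",
    "in_tree",
]


def presence_absence_report(
    invs: Sequence[Spo0Inventory],
    tree: "dendropy.Tree | str | None" = None,
) -> pd.DataFrame:
    """One row per genome with component booleans and the architecture label.

    When a tree is given, rows follow its leaf order; genomes absent from
    the tree are appended and flagged, and tree leaves without an inventory
    get a row of missing-data markers.
    """
    by_id = {inv.genome_id: inv for inv in invs}
    order: list[str] = []
    in_tree: dict[str, bool] = {}
    if tree is not None:
        dtree = _to_tree(tree)
        for leaf in dtree.leaf_node_iter():
            name = (leaf.taxon.label if leaf.taxon else "").replace(" ", "_")
            order.append(name)
            in_tree[name] = True
    for inv in invs:
        if inv.genome_id not in in_tree:
            order.append(inv.genome_id)
            in_tree[inv.genome_id] = False

    rows = []
    for gid in order:
        inv = by_id.get(gid)
        if inv is None:
            rows.append(
                dict(genome_id=gid, orphan_kinase=None, pas_orphan=None, spo0f=None,
                     spo0b=None, spo0a=None, architecture="missing", phenotype="unknown",
                     in_tree=in_tree[gid])
            )
            continue
        orphans = [k for k in inv.kinases if k.is_orphan]
        rows.append(
            dict(
                genome_id=gid,
                orphan_kinase=bool(orphans),
                pas_orphan=any(k.has_nterm_pas for k in orphans),
                spo0f=inv.spo0f is not None,
                spo0b=inv.spo0b is not None,
                spo0a=bool(inv.spo0a),
                architecture=call_architecture(inv).label,
                phenotype=inv.phenotype,
                in_tree=in_tree[gid],
            )
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def itol_annotation(report: pd.DataFrame) -> str:
    """iTOL binary dataset mirroring the component-dot scheme of the survey
    figures (orphan kinase, Spo0F, Spo0B, Spo0A per leaf)."""
    buf = StringIO()
    buf.write("DATASET_BINARY\nSEPARATOR TAB\nDATASET_LABEL\tSpo0 components\n")
    buf.write("FIELD_SHAPES\t2\t2\t2\t2\n")
    buf.write("FIELD_LABELS\torphan_kinase\tspo0F\tspo0B\tspo0A\n")
    buf.write("FIELD_COLORS\t#00cccc\t#2244cc\t#ee8800\t#22aa22\n")
    buf.write("DATA\n")
    for row in report.itertuples(index=False):
        if row.architecture == "missing":
            continue
        vals = [int(bool(v)) for v in (row.orphan_kinase, row.spo0f, row.spo0b, row.spo0a)]
        buf.write(row.genome_id + "\t" + "\t".join(str(v) for v in vals) + "\n")
    return buf.getvalue()
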