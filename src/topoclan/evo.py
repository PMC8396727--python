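"""Evolution-guided topology annotation.

Per-sequence predicted topologies are projected onto the family seed MSA
to give a multiple topology alignment; its rows are reordered by the
branching order of a phylogenetic tree; clades whose members share one
topology label become subfamilies; and a per-column majority consensus
over a subfamily gives its "initial topology". Reordering by the tree
weeds out isolated predictor errors and exposes systematic topology
variation between clades.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import dendropy

from .topology import (
    Topology,
    TopologyError,
    TopologyLabel,
    parse_topology_string,
    propagate_sides,
    topology_label,
)


class ProjectionError(ValueError):
    pass


class TreeMismatchError(ValueError):
    pass


class ConsensusError(ValueError):
    """Majority consensus could not be repaired into a valid topology."""

    def __init__(self, message: str, column_ranges: Sequence[tuple[int, int]] = ()):
        super().__init__(message)
        self.column_ranges = list(column_ranges)


@dataclass
class MultipleTopologyAlignment:
    """MSA-shaped matrix of projected per-sequence topology strings."""

    rows: dict[str, str]  # id -> gapped topology string
    tree: Optional[dendropy.Tree] = None
    row_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty topology alignment")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("rows differ in aligned length")
        if not self.row_order:
            self.row_order = list(self.rows)
        if sorted(self.row_order) != sorted(self.rows):
            raise ValueError("row_order is not a permutation of row ids")

    @property
    def column_count(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def row_ids(self) -> list[str]:
        return list(self.rows)

    def degapped(self, row_id: str) -> str:
        return self.rows[row_id].replace("-", "")


@dataclass
class TopologyGroup:
    label: TopologyLabel
    member_ids: list[str]
    supporting_clade: Optional[str] = None  # newick of the clade, if tree-derived


@dataclass
class SubfamilyPartition:
    groups: list[TopologyGroup]
    deviants: list[str]


def project_topology(msa_row: str, topology: Topology) -> str:
    """Place per-residue topology states at the non-gap columns of an MSA row."""
    states = topology.to_string()
    degapped_len = len(msa_row) - msa_row.count("-")
    if degapped_len != topology.chain_length:
        raise ProjectionError(
            f"row has {degapped_len} residues but topology covers "
            f"{topology.chain_length}"
        )
    it = iter(states)
    return "".join("-" if c == "-" else next(it) for c in msa_row)


def reorder_by_tree(mta: MultipleTopologyAlignment) -> MultipleTopologyAlignment:
    """Set row order to the left-to-right leaf order of the tree.

    Row content is untouched; only ``row_order`` changes.
    """
    if mta.tree is None:
        raise TreeMismatchError("topology alignment carries no tree")
    leaf_ids = [leaf.taxon.label for leaf in mta.tree.leaf_node_iter()]
    missing = set(mta.rows) ^ set(leaf_ids)
    if missing:
        raise TreeMismatchError(
            f"tree leaves and alignment rows differ: {sorted(missing)}"
        )
    return replace(mta, row_order=leaf_ids)


def _row_label(mta: MultipleTopologyAlignment, row_id: str) -> Optional[str]:
    try:
        return str(topology_label(parse_topology_string(mta.degapped(row_id))))
    except TopologyError:
        return None


def detect_topology_groups(
    mta: MultipleTopologyAlignment,
    min_clade_fraction: float = 0.75,
    min_group_size: int = 3,
) -> SubfamilyPartition:
    """Split a family into topology-consistent subfamilies.

    Walking the tree from the root, every maximal clade in which at least
    ``min_clade_fraction`` of the members share one topology label (and
    which has at least ``min_group_size`` members) becomes a group carrying
    that label; minority members inside such a clade, and rows in no
    qualifying clade, are flagged as deviants (putative predictor errors).
    Without a tree the split degrades to grouping by label equality.
    """
    labels = {rid: _row_label(mta, rid) for rid in mta.rows}
    groups: list[TopologyGroup] = []
    deviants: list[str] = []

    if mta.tree is None:
        by_label: dict[str, list[str]] = {}
        for rid in mta.row_order:
            lab = labels[rid]
            if lab is None:
                deviants.append(rid)
            else:
                by_label.setdefault(lab, []).append(rid)
        for lab, members in by_label.items():
            if len(members) >= min_group_size:
                groups.append(TopologyGroup(TopologyLabel.parse(lab), members))
            else:
                deviants.extend(members)
        return SubfamilyPartition(groups, deviants)

    def visit(node: dendropy.Node) -> None:
        leaf_ids = [lf.taxon.label for lf in node.leaf_iter()]
        counts = Counter(labels[rid] for rid in leaf_ids if labels[rid] is not None)
        if counts and len(leaf_ids) >= min_group_size:
            dominant, n_dom = counts.most_common(1)[0]
            if n_dom / len(leaf_ids) >= min_clade_fraction:
                members = [rid for rid in leaf_ids if labels[rid] == dominant]
                deviants.extend(rid for rid in leaf_ids if labels[rid] != dominant)
                clade_newick = node.as_newick_string() if hasattr(node, "as_newick_string") else None
                groups.append(
                    TopologyGroup(TopologyLabel.parse(dominant), members, clade_newick)
                )
                return
        if node.is_leaf():
            deviants.append(node.taxon.label)
            return
        for child in node.child_nodes():
            visit(child)

    visit(mta.tree.seed_node)
    return SubfamilyPartition(groups, deviants)


def pick_representative(mta: MultipleTopologyAlignment, member_ids: Sequence[str]) -> str:
    """Group representative: fewest gaps, ties broken by id."""
    return min(member_ids, key=lambda rid: (mta.rows[rid].count("-"), rid))


def consensus_topology(
    mta: MultipleTopologyAlignment,
    member_ids: Optional[Sequence[str]] = None,
    representative: Optional[str] = None,
    min_run: int = 5,
) -> Topology:
    """Per-column majority topology of a subfamily (the "initial topology").

    The column-wise majority state over the group rows is degapped on the
    representative row, runs shorter than ``min_run`` are merged into their
    flanking state, and loop sides are re-propagated from the majority
    N-terminal side, so small prediction disagreements cannot break the
    side-alternation invariant.
    """
    ids = list(member_ids) if member_ids is not None else list(mta.row_order)
    if not ids:
        raise ConsensusError("empty group")
    rep = representative or pick_representative(mta, ids)
    rows = [mta.rows[rid] for rid in ids]
    rep_row = mta.rows[rep]

    # column-wise majority among residue states; ties (and gap majorities at
    # representative residue columns) resolve toward the representative row
    consensus_chars: list[str] = []
    for col in range(mta.column_count):
        if rep_row[col] == "-":
            continue
        counts = Counter(row[col] for row in rows if row[col] != "-")
        if not counts:
            consensus_chars.append(rep_row[col])
            continue
        top = counts.most_common()
        best = top[0][1]
        tied = sorted(ch for ch, n in top if n == best)
        consensus_chars.append(rep_row[col] if rep_row[col] in tied else tied[0])
    raw = "".join(consensus_chars)

    smoothed = _smooth(raw, min_run)
    n_side = _majority_n_term_side(rows, rep_row)
    skeleton = "".join("L" if c in "io" else c for c in smoothed)
    repaired = propagate_sides(skeleton, n_side)
    try:
        t = parse_topology_string(repaired, source="consensus")
    except TopologyError as exc:
        ranges = _run_ranges(repaired)
        raise ConsensusError(f"irreparable consensus: {exc}", ranges) from exc
    return t


def _majority_n_term_side(rows: Sequence[str], rep_row: str) -> str:
    votes = Counter()
    for row in rows:
        for c in row:
            if c in "io":
                votes["Nin" if c == "i" else "Nout"] += 1
                break
    if not votes:
        raise ConsensusError("no sided residues in any row")
    top = votes.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        for c in rep_row:
            if c in "io":
                return "Nin" if c == "i" else "Nout"
    return top[0][0]


def _smooth(states: str, min_run: int) -> str:
    """Merge runs shorter than ``min_run`` into a flanking run.

    The shortest (leftmost among equals) offending run is relabelled with
    the longer flanking run's state (ties toward the preceding run) until
    every interior run is at least ``min_run`` long.
    """
    chars = list(states)
    while True:
        runs = _run_ranges("".join(chars))
        offenders = [
            (e - s + 1, i)
            for i, (s, e) in enumerate(runs)
            if e - s + 1 < min_run
            and len(runs) > 1
            # terminal loop runs are tails, not noise blips: keep them
            and not (i in (0, len(runs) - 1) and chars[s] in "ioS")
        ]
        if not offenders:
            break
        _, idx = min(offenders)
        s, e = runs[idx]
        if idx == 0:
            fill = chars[runs[1][0]]
        elif idx == len(runs) - 1:
            fill = chars[runs[idx - 1][0]]
        else:
            left_len = runs[idx - 1][1] - runs[idx - 1][0] + 1
            right_len = runs[idx + 1][1] - runs[idx + 1][0] + 1
            fill = chars[runs[idx - 1][0]] if left_len >= right_len else chars[runs[idx + 1][0]]
        for k in range(s, e + 1):
            chars[k] = fill
    return "".join(chars)


def _run_ranges(s: str) -> list[tuple[int, int]]:
    ranges: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(s) + 1):
        if i == len(s) or s[i] != s[start]:
            ranges.append((start, i - 1))
            start = i
    return ranges
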