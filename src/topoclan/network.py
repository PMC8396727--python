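"""E-value-weighted family/repeat homology networks.

Pairwise profile-search hits between families (or their N-/C-terminal
repeat units) are deduplicated — of a bidirectional pair the record with
the lowest E-value survives — and turned into an undirected weighted
graph: edges exist below E = 0.1, are classed *thick* below E = 0.001 and
*thin* otherwise, and carry weight log10(E).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import math

import networkx as nx

from .topology import RepeatAnnotation


@dataclass(frozen=True)
class FamilyHitRecord:
    query: str  # unit id: family, family:N or family:C
    hit: str
    e_value: float
    hit_span: Optional[tuple[int, int]] = None  # aligned span on the hit sequence

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")


def assign_hit_repeat(hit: FamilyHitRecord, hit_repeats: RepeatAnnotation) -> str:
    """Unit id of the hit with its repeat role resolved from the aligned span.

    The role is the repeat containing the majority of the hit-side span;
    'full' (tie flagged in the id as ':full') when the span covers both
    repeats equally.
    """
    if hit.hit_span is None:
        raise ValueError("hit record carries no aligned span")
    s, e = hit.hit_span
    if s > e or s < 1:
        raise ValueError(f"bad span {hit.hit_span}")
    (ns, ne), (cs, ce) = hit_repeats.n_repeat, hit_repeats.c_repeat
    if e > ce:
        raise ValueError(f"span {hit.hit_span} outside chain (ends at {ce})")
    ov_n = max(0, min(e, ne) - max(s, ns) + 1)
    ov_c = max(0, min(e, ce) - max(s, cs) + 1)
    family = hit.hit.split(":")[0]
    if ov_n > ov_c:
        return f"{family}:N"
    if ov_c > ov_n:
        return f"{family}:C"
    return f"{family}:full"


def dedupe_bidirectional(hits: Iterable[FamilyHitRecord]) -> list[FamilyHitRecord]:
    """One record per unordered query/hit pair, keeping the lowest E-value."""
    best: dict[frozenset[str], FamilyHitRecord] = {}
    order: list[frozenset[str]] = []
    for h in hits:
        key = frozenset((h.query, h.hit))
        if key not in best:
            best[key] = h
            order.append(key)
        elif h.e_value < best[key].e_value:
            best[key] = h
    return [best[k] for k in order]


def build_network(
    hits: Sequence[FamilyHitRecord],
    nodes: Iterable[str] = (),
    e_threshold: float = 0.1,
    thick_threshold: float = 0.001,
    fold_types: Optional[dict[str, str]] = None,
) -> nx.Graph:
    """Weighted family network from deduplicated hits.

    Edges require ``e_value < e_threshold``; weight is log10(E) (negative
    for significant hits, stored raw); class is 'thick' below
    ``thick_threshold`` else 'thin'. ``nodes`` declares families so that
    isolated ones still appear.
    """
    g = nx.Graph()
    for node in nodes:
        g.add_node(node)
    for h in hits:
        for end in (h.query, h.hit):
            if end not in g:
                g.add_node(end)
    for h in hits:
        if h.e_value >= e_threshold:
            continue
        cls = "thick" if h.e_value < thick_threshold else "thin"
        existing = g.get_edge_data(h.query, h.hit)
        if existing is not None and existing["e_value"] <= h.e_value:
            continue
        g.add_edge(
            h.query,
            h.hit,
            e_value=h.e_value,
            weight=math.log10(h.e_value),
            edge_class=cls,
        )
    for node in g.nodes:
        family, _, role = node.partition(":")
        g.nodes[node]["role"] = role or "full"
        g.nodes[node]["fold_type"] = (fold_types or {}).get(family, "")
    return g


def edge_table(g: nx.Graph) -> list[dict]:
    rows = []
    for u, v, data in sorted(g.edges(data=True)):
        rows.append(
            {
                "a": u,
                "b": v,
                "e_value": data["e_value"],
                "weight": data["weight"],
                "edge_class": data["edge_class"],
            }
        )
    return rows
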