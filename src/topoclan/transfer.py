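"""Template-guided topology refinement.

A family's "initial" consensus topology is compared with the topology of
a homologous family of known structure through a pairwise alignment.
Template helices are classified as aligned / gap / loop-opposed; helices
the predictor missed (template TM, broken or reentrant helices opposite
query loops) are inserted, loop sides are re-propagated from the
N-terminus, and scaffold/core subdomain and repeat-unit annotations are
transferred across the aligned helix map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .topology import (
    HELIX_KINDS,
    LOOP_KINDS,
    RepeatAnnotation,
    Segment,
    SegmentKind,
    Topology,
    TopologyError,
    parse_topology_string,
    propagate_sides,
)

MIN_ALIGNED_OVERLAP = 5  # residues of both helices that must be aligned


class CoordinateError(ValueError):
    pass


class AmbiguousTypeError(ValueError):
    """Best broken and reentrant template hits tie exactly; KR-bias must decide."""


class InferenceConflictError(ValueError):
    pass


class TransferRefusedError(ValueError):
    pass


@dataclass
class PairwiseAlignment:
    """Residue-level query-template alignment with its E-value.

    ``columns`` is the gapped alignment, one (q_pos, t_pos) pair per
    column with ``None`` marking a gap on that side; positions are
    1-based and strictly increasing along each side.
    """

    query_id: str
    template_id: str
    columns: list[tuple[Optional[int], Optional[int]]]
    e_value: float
    identity: float = 0.0

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")
        for side in (0, 1):
            seq = [c[side] for c in self.columns if c[side] is not None]
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError("alignment positions must be strictly increasing")

    @classmethod
    def from_gapped(
        cls,
        query_id: str,
        template_id: str,
        q_aln: str,
        t_aln: str,
        e_value: float,
        identity: float = 0.0,
        q_start: int = 1,
        t_start: int = 1,
    ) -> "PairwiseAlignment":
        if len(q_aln) != len(t_aln):
            raise ValueError("gapped strings differ in length")
        cols: list[tuple[Optional[int], Optional[int]]] = []
        q, t = q_start - 1, t_start - 1
        for qc, tc in zip(q_aln, t_aln):
            qp = tp = None
            if qc != "-":
                q += 1
                qp = q
            if tc != "-":
                t += 1
                tp = t
            if qp is not None or tp is not None:
                cols.append((qp, tp))
        return cls(query_id, template_id, cols, e_value, identity)

    @property
    def aligned_pairs(self) -> list[tuple[int, int]]:
        return [(q, t) for q, t in self.columns if q is not None and t is not None]

    @property
    def aligned_columns(self) -> int:
        return len(self.aligned_pairs)


@dataclass
class HelixAlignmentRecord:
    template_helix_index: int
    template_kind: SegmentKind
    cls: str  # aligned | gap | inside_loop | outside_loop | signal_peptide
    overlap_residues: int
    query_span: Optional[tuple[int, int]] = None
    query_helix_index: Optional[int] = None


_STATE_OF_KIND = {
    SegmentKind.INSIDE_LOOP: "inside_loop",
    SegmentKind.OUTSIDE_LOOP: "outside_loop",
    SegmentKind.SIGNAL_PEPTIDE: "signal_peptide",
}
#: tie-break precedence for the dominating-composition rule (rarest last)
_PRECEDENCE = ["gap", "inside_loop", "outside_loop", "signal_peptide"]


def classify_helices(
    aln: PairwiseAlignment, q_topology: Topology, t_topology: Topology
) -> list[HelixAlignmentRecord]:
    """Classify every template helix against the query topology.

    A helix is *aligned* when at least five residues of both helices are
    aligned; otherwise its class is the dominating query state (gap,
    inside loop, outside loop or signal peptide) over the template-helix
    columns, ties broken by the precedence gap > loop > signal peptide.
    """
    for q, t in aln.aligned_pairs:
        if not (q_topology.first_residue <= q <= q_topology.last_residue):
            raise CoordinateError(f"query position {q} outside chain")
        if not (t_topology.first_residue <= t <= t_topology.last_residue):
            raise CoordinateError(f"template position {t} outside chain")

    q_helices = q_topology.helices()
    records: list[HelixAlignmentRecord] = []
    for k, th in enumerate(t_topology.helices()):
        cols = [(q, t) for q, t in aln.columns if t is not None and th.start <= t <= th.end]
        per_helix = [0] * len(q_helices)
        state_counts = {s: 0 for s in _PRECEDENCE}
        q_positions = [q for q, _ in cols if q is not None]
        for q, _ in cols:
            if q is None:
                state_counts["gap"] += 1
                continue
            seg = q_topology.segment_at(q)
            if seg.kind in HELIX_KINDS:
                for j, qh in enumerate(q_helices):
                    if qh.start <= q <= qh.end:
                        per_helix[j] += 1
                        break
            else:
                state_counts[_STATE_OF_KIND[seg.kind]] += 1
        best_overlap = max(per_helix, default=0)
        span = (min(q_positions), max(q_positions)) if q_positions else None
        if best_overlap >= MIN_ALIGNED_OVERLAP:
            j = per_helix.index(best_overlap)
            records.append(
                HelixAlignmentRecord(k, th.kind, "aligned", best_overlap, span, j)
            )
        else:
            total = sum(state_counts.values())
            if total == 0:
                cls = "gap"
            else:
                best = max(state_counts.values())
                cls = next(s for s in _PRECEDENCE if state_counts[s] == best)
            records.append(HelixAlignmentRecord(k, th.kind, cls, best_overlap, span))
    return records


def choose_transporter_type(hits: Sequence[tuple[str, float]]) -> str:
    """Pick broken vs reentrant from the best (lowest E-value) template hit."""
    if not hits:
        raise ValueError("no template hits")
    best_e = min(e for _, e in hits)
    best_types = {t for t, e in hits if e == best_e}
    if len(best_types) > 1:
        raise AmbiguousTypeError(
            f"broken and reentrant templates tie at E={best_e}; "
            "KR-bias arbitration required"
        )
    return best_types.pop()


def infer_final_topology(
    q_initial: Topology,
    t_topology: Topology,
    records: Sequence[HelixAlignmentRecord],
    aln: PairwiseAlignment,
) -> Topology:
    """Insert template helices that the query prediction missed.

    Every template helix classified as opposing a query loop is inserted
    into that loop at the aligned span (clipped to the loop, minimum 5
    residues), after which all downstream loop sides are re-propagated
    from the query's N-terminal side. Idempotent: re-running on the
    result inserts nothing.
    """
    chars = list(q_initial.to_string())
    offset = q_initial.first_residue
    t_helices = t_topology.helices()
    kind_char = {
        SegmentKind.TM_HELIX: "M",
        SegmentKind.BROKEN_HELIX: "B",
        SegmentKind.REENTRANT_HELIX: "R",
    }
    for rec in records:
        if rec.cls not in ("inside_loop", "outside_loop"):
            continue
        if rec.query_span is None:
            continue
        th = t_helices[rec.template_helix_index]
        qs, qe = rec.query_span
        loop = _host_loop(q_initial, qs, qe)
        if loop is None:
            raise InferenceConflictError(
                f"template helix {rec.template_helix_index} maps to "
                f"{qs}-{qe} which overlaps no query loop"
            )
        s = max(qs, loop.start + 1)  # keep >=1 loop residue on each side
        e = min(qe, loop.end - 1)
        want = th.length
        while e - s + 1 < min(want, MIN_ALIGNED_OVERLAP):
            grew = False
            if s > loop.start + 1:
                s -= 1
                grew = True
            if e < loop.end - 1 and e - s + 1 < want:
                e += 1
                grew = True
            if not grew:
                break
        if e - s + 1 < MIN_ALIGNED_OVERLAP:
            raise InferenceConflictError(
                f"loop {loop.start}-{loop.end} too short to host a "
                f"{th.kind.value} of length {th.length}"
            )
        e = min(e, s + want - 1)
        for pos in range(s, e + 1):
            chars[pos - offset] = kind_char[th.kind]
    skeleton = "".join("L" if c in "io" else c for c in chars)
    repaired = propagate_sides(skeleton, q_initial.n_term_side)
    try:
        final = parse_topology_string(repaired, source="final")
    except TopologyError as exc:
        raise InferenceConflictError(f"inference produced invalid topology: {exc}") from exc
    if q_initial.first_residue != 1:
        final = Topology(
            chain_length=final.chain_length,
            segments=[
                Segment(
                    s.kind,
                    s.start + q_initial.first_residue - 1,
                    s.end + q_initial.first_residue - 1,
                    orientation=s.orientation,
                    reentrant_side=s.reentrant_side,
                )
                for s in final.segments
            ],
            source="final",
            first_residue=q_initial.first_residue,
        )
    return final


def _host_loop(t: Topology, qs: int, qe: int) -> Optional[Segment]:
    """Query loop overlapping most of span [qs, qe]."""
    best: Optional[Segment] = None
    best_ov = 0
    for seg in t.segments:
        if seg.kind not in LOOP_KINDS:
            continue
        ov = min(seg.end, qe) - max(seg.start, qs) + 1
        if ov > best_ov:
            best, best_ov = seg, ov
    return best


def transfer_subdomains(
    t_annotation: RepeatAnnotation,
    records: Sequence[HelixAlignmentRecord],
    q_final: Topology,
    t_topology: Topology,
    min_aligned_fraction: float = 0.5,
) -> RepeatAnnotation:
    """Carry scaffold/core and repeat-unit tags from template to query.

    Each aligned query helix inherits its template partner's tags;
    unaligned query helices inherit from the nearest aligned neighbour
    and are flagged as extrapolated. When the query's N-terminal helices
    systematically align to the template's C-repeat (and vice versa), the
    repeat units have been shuffled: tags still follow the template and
    the annotation is flagged. Transfer is refused when fewer than half
    of the template helices are aligned.
    """
    t_helices = t_topology.helices()
    t_roles = t_annotation.helix_repeat_roles(t_topology)
    aligned = [r for r in records if r.cls == "aligned" and r.query_helix_index is not None]
    if len(t_helices) == 0 or len(aligned) / len(t_helices) < min_aligned_fraction:
        raise TransferRefusedError(
            f"only {len(aligned)}/{len(t_helices)} template helices aligned"
        )

    q_helices = q_final.helices()
    tags: list[Optional[str]] = [None] * len(q_helices)
    roles: list[Optional[str]] = [None] * len(q_helices)
    for rec in aligned:
        j = rec.query_helix_index
        tags[j] = t_annotation.helix_tags[rec.template_helix_index]
        roles[j] = t_roles[rec.template_helix_index]

    extrapolated: set[int] = set()
    for j in range(len(q_helices)):
        if tags[j] is not None:
            continue
        neighbours = sorted(
            (k for k in range(len(q_helices)) if tags[k] is not None),
            key=lambda k: (abs(k - j), k),
        )
        same_repeat = [k for k in neighbours if roles[k] == _positional_role(j, roles)]
        src = same_repeat[0] if same_repeat else neighbours[0]
        tags[j] = tags[src]
        roles[j] = roles[src]
        extrapolated.add(j)

    # shuffle detection: inherited roles contradict chain-order expectation
    # (query helices in the N-terminal half inheriting template C-repeat
    # tags, or vice versa) for the majority of aligned helices
    mismatch = match = 0
    for rec in aligned:
        j = rec.query_helix_index
        positional = "N" if j < len(q_helices) / 2 else "C"
        inherited = t_roles[rec.template_helix_index]
        if inherited in ("N", "C"):
            if inherited == positional:
                match += 1
            else:
                mismatch += 1
    shuffled = mismatch > match

    n_span, c_span = _repeat_spans(q_final, roles, shuffled)
    return RepeatAnnotation(
        n_repeat=n_span,
        c_repeat=c_span,
        helix_tags=[t or "scaffold" for t in tags],
        extrapolated=extrapolated,
        shuffled=shuffled,
    )


def _positional_role(j: int, roles: Sequence[Optional[str]]) -> Optional[str]:
    known = [(k, r) for k, r in enumerate(roles) if r in ("N", "C")]
    if not known:
        return None
    return min(known, key=lambda kr: abs(kr[0] - j))[1]


def _repeat_spans(
    q_final: Topology, roles: Sequence[Optional[str]], shuffled: bool
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Positional repeat spans: first helix block vs second, cut at a loop."""
    q_helices = q_final.helices()
    labelled = [(j, r) for j, r in enumerate(roles) if r in ("N", "C")]
    if not labelled:
        raise TransferRefusedError("no repeat roles transferred")
    first_role = labelled[0][1]
    switch = next((j for j, r in labelled if r != first_role), None)
    if switch is None:
        mid_helix = len(q_helices) // 2
    else:
        mid_helix = switch
    cut_lo = q_helices[mid_helix - 1].end if mid_helix > 0 else q_final.first_residue
    cut_hi = q_helices[mid_helix].start if mid_helix < len(q_helices) else q_final.last_residue
    cut = (cut_lo + cut_hi) // 2
    return (
        (q_final.first_residue, cut),
        (cut + 1, q_final.last_residue),
    )


@dataclass
class RepeatHit:
    """One internal-repeat alignment hit with the repeat roles of both sides."""

    query_role: str  # N | C
    hit_role: str  # N | C
    e_value: float


def repeat_similarity(self_hits: Sequence[RepeatHit]) -> Optional[float]:
    """Best (minimum) E-value among N-vs-C repeat hits; None when absent."""
    n_vs_c = [
        h.e_value for h in self_hits if {h.query_role, h.hit_role} == {"N", "C"}
    ]
    return min(n_vs_c) if n_vs_c else None
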