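"""Positive-inside-rule (KR-bias) statistics and topology-model selection.

Cytoplasmic loops of membrane proteins are enriched in lysine and
arginine. Counting K/R in membrane-adjacent windows — up to 10 residues
inside each helix end and up to 25 loop residues beyond it — under two
candidate topology models (one broken-helix, one reentrant) and comparing
the family-mean inside-minus-outside bias selects the model the positive-
inside rule supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .topology import (
    CROSSING_KINDS,
    LOOP_KINDS,
    RepeatAnnotation,
    Segment,
    SegmentKind,
    Topology,
)


@dataclass(frozen=True)
class KRWindowParams:
    inside_helix_depth: int = 10  # residues counted inside each helix end
    after_helix_extent: int = 25  # loop residues counted beyond the helix

    def __post_init__(self) -> None:
        if self.inside_helix_depth <= 0 or self.after_helix_extent <= 0:
            raise ValueError("window extents must be positive")


Window = tuple[str, tuple[int, ...]]  # (side 'i'/'o', sorted positions)


def _flank_positions(t: Topology, seg: Segment, before: bool, extent: int) -> list[int]:
    """Loop positions adjacent to a helix flank, truncated at the next segment."""
    idx = t.segments.index(seg)
    neighbour = (
        t.segments[idx - 1] if before and idx > 0 else
        t.segments[idx + 1] if not before and idx + 1 < len(t.segments) else None
    )
    if neighbour is None or neighbour.kind not in LOOP_KINDS:
        return []
    if before:
        lo = max(neighbour.start, seg.start - extent)
        return list(range(lo, seg.start))
    hi = min(neighbour.end, seg.end + extent)
    return list(range(seg.end + 1, hi + 1))


def _helix_windows(t: Topology, seg: Segment, params: KRWindowParams) -> list[Window]:
    depth = min(params.inside_helix_depth, seg.length)
    head = list(range(seg.start, seg.start + depth))
    tail = list(range(seg.end - depth + 1, seg.end + 1))
    if seg.kind in CROSSING_KINDS:
        entry = "i" if seg.orientation == "in_to_out" else "o"
        exit_ = "o" if entry == "i" else "i"
        win_entry = _flank_positions(t, seg, True, params.after_helix_extent) + head
        win_exit = tail + _flank_positions(t, seg, False, params.after_helix_extent)
        return [(entry, tuple(sorted(win_entry))), (exit_, tuple(sorted(win_exit)))]
    if seg.kind is SegmentKind.REENTRANT_HELIX:
        pos = (
            _flank_positions(t, seg, True, params.after_helix_extent)
            + head
            + tail
            + _flank_positions(t, seg, False, params.after_helix_extent)
        )
        return [(seg.side, tuple(sorted(set(pos))))]
    return []


def loop_windows(
    t: Topology, params: KRWindowParams = KRWindowParams()
) -> list[Window]:
    """Membrane-adjacent K/R counting windows, one (or two) per helix.

    TM and broken helices contribute an entry-side and an exit-side
    window; a reentrant helix contributes a single window on its shared
    entry/exit side.
    """
    windows: list[Window] = []
    for seg in t.helices():
        windows.extend(_helix_windows(t, seg, params))
    return windows


def _count_kr(seq: str, positions: set[int], offset: int) -> int:
    return sum(1 for p in positions if seq[p - offset].upper() in "KR")


def kr_bias(
    seq: str,
    t: Topology,
    params: KRWindowParams = KRWindowParams(),
    windows: Optional[Sequence[Window]] = None,
) -> tuple[int, int, int]:
    """(inside_kr, outside_kr, bias) over the topology's counting windows.

    Overlapping windows on the same side count each position once;
    ``bias = inside_kr - outside_kr``.
    """
    if len(seq) != t.chain_length:
        raise ValueError(
            f"sequence length {len(seq)} != chain length {t.chain_length}"
        )
    wins = loop_windows(t, params) if windows is None else windows
    inside: set[int] = set()
    outside: set[int] = set()
    for side, pos in wins:
        (inside if side == "i" else outside).update(pos)
    i_kr = _count_kr(seq, inside, t.first_residue)
    o_kr = _count_kr(seq, outside, t.first_residue)
    return i_kr, o_kr, i_kr - o_kr


@dataclass
class KRBiasProfile:
    """Per-sequence KR counts under two candidate topology models."""

    per_sequence: dict[str, dict[str, tuple[int, int, int]]] = field(default_factory=dict)
    mean_bias: dict[str, float] = field(default_factory=dict)
    selected_model: str = "ambiguous"  # broken | reentrant | ambiguous
    skipped: list[str] = field(default_factory=list)


def _window_columns(rep_row: str, windows: Sequence[Window]) -> list[tuple[str, list[int]]]:
    """Map representative residue positions (1-based) to MSA columns."""
    res_to_col: dict[int, int] = {}
    res = 0
    for col, ch in enumerate(rep_row):
        if ch != "-":
            res += 1
            res_to_col[res] = col
    return [(side, [res_to_col[p] for p in pos if p in res_to_col]) for side, pos in windows]


def select_topology_model(
    family_msa: dict[str, str],
    representative_id: str,
    model_broken: Topology,
    model_reentrant: Topology,
    params: KRWindowParams = KRWindowParams(),
    tolerance: float = 0.5,
    max_gap_fraction: float = 0.5,
) -> KRBiasProfile:
    """Select broken vs reentrant topology by the higher family-mean KR bias.

    Both models live on the representative sequence's coordinates; every
    MSA row is mapped onto them through the alignment columns. Rows with
    more than ``max_gap_fraction`` gaps inside the window regions are
    skipped. The verdict is 'ambiguous' when the means differ by less
    than ``tolerance``.
    """
    if not family_msa:
        raise ValueError("empty family MSA")
    rep_row = family_msa[representative_id]
    models = {"broken": model_broken, "reentrant": model_reentrant}
    model_cols = {
        name: _window_columns(rep_row, loop_windows(model, params))
        for name, model in models.items()
    }
    profile = KRBiasProfile()
    sums = {"broken": 0.0, "reentrant": 0.0}
    n_used = 0
    for rid, row in family_msa.items():
        all_cols = sorted(
            {c for wins in model_cols.values() for _, cols in wins for c in cols}
        )
        if all_cols:
            gap_frac = sum(1 for c in all_cols if row[c] == "-") / len(all_cols)
            if gap_frac > max_gap_fraction:
                profile.skipped.append(rid)
                continue
        entry: dict[str, tuple[int, int, int]] = {}
        for name, wins in model_cols.items():
            inside: set[int] = set()
            outside: set[int] = set()
            for side, cols in wins:
                (inside if side == "i" else outside).update(cols)
            i_kr = sum(1 for c in inside if row[c].upper() in "KR")
            o_kr = sum(1 for c in outside if row[c].upper() in "KR")
            entry[name] = (i_kr, o_kr, i_kr - o_kr)
            sums[name] += i_kr - o_kr
        profile.per_sequence[rid] = entry
        n_used += 1
    if n_used == 0:
        raise ValueError("all rows skipped (too gappy in window regions)")
    profile.mean_bias = {name: sums[name] / n_used for name in sums}
    delta = profile.mean_bias["broken"] - profile.mean_bias["reentrant"]
    if abs(delta) < tolerance:
        profile.selected_model = "ambiguous"
    else:
        profile.selected_model = "broken" if delta > 0 else "reentrant"
    return profile


def core_helix_krbias(
    seq: str,
    t: Topology,
    annotation: RepeatAnnotation,
    params: KRWindowParams = KRWindowParams(),
) -> dict[str, int]:
    """KR bias of the last core helix of each repeat unit.

    Returns ``{'N': bias, 'C': bias}`` with the bias computed over that
    helix's windows only.
    """
    if not annotation.helix_tags:
        raise ValueError("repeat annotation carries no subdomain tags")
    helices = t.helices()
    if len(annotation.helix_tags) != len(helices):
        raise ValueError("helix_tags length does not match helix count")
    roles = annotation.helix_repeat_roles(t)
    result: dict[str, int] = {}
    for repeat in ("N", "C"):
        core = [
            h
            for h, tag, role in zip(helices, annotation.helix_tags, roles)
            if tag == "core" and role == repeat
        ]
        if not core:
            raise ValueError(f"no core helices annotated in the {repeat}-repeat")
        wins = _helix_windows(t, core[-1], params)
        _, _, bias = kr_bias(seq, t, params, windows=wins)
        result[repeat] = bias
    return result
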