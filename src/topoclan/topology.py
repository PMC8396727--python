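"""Core data model for membrane-protein topologies.

A topology is an ordered, gap-free segmentation of one protein chain into
inside/outside loops, canonical transmembrane (TM) helices, non-canonical
helices (broken or reentrant) and an optional N-terminal signal peptide.
The per-residue encoding follows the TOPCONS convention (``i`` inside,
``o`` outside, ``M`` membrane helix) extended with ``B`` (broken helix,
a membrane-crossing helix with a mid-membrane discontinuity), ``R``
(reentrant helix, entering and exiting on the same side) and ``S``
(signal peptide).

Coordinates are 1-based and inclusive throughout.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional


class TopologyError(ValueError):
    """Base class for topology model violations."""


class TopologyInconsistencyError(TopologyError):
    """Segment arrangement violates side alternation or segment geometry."""


class UnsupportedMixtureError(TopologyError):
    """A single chain mixes broken and reentrant helices."""


class RepeatBoundaryError(TopologyError):
    """A repeat boundary falls inside a helix."""


class ShortTMHelixWarning(UserWarning):
    """A parsed TM helix is shorter than the typical bilayer-spanning length."""


class SegmentKind(str, Enum):
    INSIDE_LOOP = "inside_loop"
    OUTSIDE_LOOP = "outside_loop"
    TM_HELIX = "tm_helix"
    BROKEN_HELIX = "broken_helix"
    REENTRANT_HELIX = "reentrant_helix"
    SIGNAL_PEPTIDE = "signal_peptide"


LOOP_KINDS = frozenset({SegmentKind.INSIDE_LOOP, SegmentKind.OUTSIDE_LOOP})
HELIX_KINDS = frozenset(
    {SegmentKind.TM_HELIX, SegmentKind.BROKEN_HELIX, SegmentKind.REENTRANT_HELIX}
)
#: Helix kinds that cross the membrane and therefore flip the loop side.
CROSSING_KINDS = frozenset({SegmentKind.TM_HELIX, SegmentKind.BROKEN_HELIX})

_KIND_TO_CHAR = {
    SegmentKind.INSIDE_LOOP: "i",
    SegmentKind.OUTSIDE_LOOP: "o",
    SegmentKind.TM_HELIX: "M",
    SegmentKind.BROKEN_HELIX: "B",
    SegmentKind.REENTRANT_HELIX: "R",
    SegmentKind.SIGNAL_PEPTIDE: "S",
}
_CHAR_TO_KIND = {v: k for k, v in _KIND_TO_CHAR.items()}

MIN_HELIX_LEN = 5
TYPICAL_TM_LEN = 12


@dataclass(frozen=True)
class Segment:
    kind: SegmentKind
    start: int
    end: int
    orientation: str = "none"  # in_to_out | out_to_in | none
    reentrant_side: str = "none"  # in_in | out_out | none
    break_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise TopologyInconsistencyError(
                f"segment {self.kind.value} has start {self.start} > end {self.end}"
            )
        if self.break_pos is not None and not (self.start < self.break_pos < self.end):
            raise TopologyInconsistencyError(
                f"break_pos {self.break_pos} not strictly inside "
                f"({self.start},{self.end})"
            )
        crossing = self.kind in CROSSING_KINDS
        if crossing and self.orientation not in ("in_to_out", "out_to_in"):
            raise TopologyInconsistencyError(
                f"{self.kind.value} {self.start}-{self.end} needs an orientation"
            )
        if not crossing and self.orientation != "none":
            raise TopologyInconsistencyError(
                f"{self.kind.value} {self.start}-{self.end} cannot carry an orientation"
            )
        if self.kind is SegmentKind.REENTRANT_HELIX and self.reentrant_side not in (
            "in_in",
            "out_out",
        ):
            raise TopologyInconsistencyError(
                f"reentrant helix {self.start}-{self.end} needs a reentrant_side"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def side(self) -> Optional[str]:
        """Loop side ('i'/'o') for loops, entry side for reentrant helices."""
        if self.kind is SegmentKind.INSIDE_LOOP:
            return "i"
        if self.kind is SegmentKind.OUTSIDE_LOOP:
            return "o"
        if self.kind is SegmentKind.REENTRANT_HELIX:
            return "i" if self.reentrant_side == "in_in" else "o"
        return None


@dataclass
class Topology:
    """Validated segmentation of residues ``first_residue .. last_residue``.

    ``first_residue`` is 1 for whole chains; repeat-unit slices produced by
    :func:`split_repeats` keep their absolute coordinates by shifting it.
    """

    chain_length: int
    segments: list[Segment] = field(default_factory=list)
    source: str = "predicted"  # predicted | consensus | template | final
    first_residue: int = 1

    def __post_init__(self) -> None:
        self.validate()

    # -- geometry ---------------------------------------------------------
    @property
    def last_residue(self) -> int:
        return self.first_residue + self.chain_length - 1

    def validate(self) -> None:
        if self.chain_length <= 0:
            raise TopologyInconsistencyError("chain_length must be positive")
        if not self.segments:
            raise TopologyInconsistencyError("topology has no segments")
        pos = self.first_residue
        for seg in self.segments:
            if seg.start != pos:
                raise TopologyInconsistencyError(
                    f"segment {seg.kind.value} starts at {seg.start}, expected {pos}"
                )
            pos = seg.end + 1
        if pos - 1 != self.last_residue:
            raise TopologyInconsistencyError(
                f"segments end at {pos - 1}, chain ends at {self.last_residue}"
            )
        self._check_alternation()

    def _check_alternation(self) -> None:
        prev: Optional[Segment] = None
        for seg in self.segments:
            if prev is not None:
                if seg.kind in LOOP_KINDS and prev.kind in LOOP_KINDS:
                    raise TopologyInconsistencyError(
                        f"adjacent loop segments at {prev.start}-{prev.end} and "
                        f"{seg.start}-{seg.end} (side change without crossing)"
                        if seg.kind is not prev.kind
                        else f"unmerged same-side loops at {seg.start}"
                    )
            prev = seg
        # walk sides through the chain
        side: Optional[str] = None
        for seg in self.segments:
            if seg.kind in LOOP_KINDS:
                if side is not None and seg.side != side:
                    raise TopologyInconsistencyError(
                        f"loop {seg.start}-{seg.end} on side '{seg.side}' but the "
                        f"preceding crossings imply side '{side}'"
                    )
                side = seg.side
            elif seg.kind in CROSSING_KINDS:
                expect = {"in_to_out": "i", "out_to_in": "o"}[seg.orientation]
                if side is not None and side != expect:
                    raise TopologyInconsistencyError(
                        f"{seg.kind.value} {seg.start}-{seg.end} oriented "
                        f"{seg.orientation} but entered from side '{side}'"
                    )
                side = "o" if expect == "i" else "i"
            elif seg.kind is SegmentKind.REENTRANT_HELIX:
                if side is not None and seg.side != side:
                    raise TopologyInconsistencyError(
                        f"reentrant helix {seg.start}-{seg.end} marked "
                        f"{seg.reentrant_side} but flanked by side '{side}'"
                    )
                side = seg.side
            # signal peptide: side-neutral

    # -- views ------------------------------------------------------------
    def helices(self) -> list[Segment]:
        """Membrane helices (TM, broken, reentrant) in chain order.

        Signal peptides are excluded from all helix counts.
        """
        return [s for s in self.segments if s.kind in HELIX_KINDS]

    def loops(self) -> list[Segment]:
        return [s for s in self.segments if s.kind in LOOP_KINDS]

    @property
    def n_term_side(self) -> str:
        """'Nin' or 'Nout' from the side of the first sided segment."""
        for seg in self.segments:
            if seg.side is not None:
                return "Nin" if seg.side == "i" else "Nout"
        raise TopologyInconsistencyError("no sided segment to orient the N-terminus")

    def segment_at(self, pos: int) -> Segment:
        for seg in self.segments:
            if seg.start <= pos <= seg.end:
                return seg
        raise TopologyError(
            f"position {pos} outside chain "
            f"{self.first_residue}..{self.last_residue}"
        )

    def to_string(self) -> str:
        """Per-residue one-letter encoding; inverse of parse_topology_string."""
        out: list[str] = []
        for seg in self.segments:
            out.append(_KIND_TO_CHAR[seg.kind] * seg.length)
        return "".join(out)

    def states(self) -> str:
        return self.to_string()


def parse_topology_string(string: str, source: str = "predicted") -> Topology:
    """Parse a per-residue topology string over ``{i,o,M,B,R,S}``.

    Raises :class:`TopologyInconsistencyError` when side alternation is
    violated (e.g. a TM helix flanked by the same side twice), when a helix
    run is shorter than 5 residues, or when a helix touches a chain terminus
    (helix runs must be flanked by loop runs).
    """
    if not string:
        raise TopologyError("empty topology string")
    bad = set(string) - set(_CHAR_TO_KIND)
    if bad:
        raise TopologyError(f"unknown topology characters: {sorted(bad)}")

    runs = [(m.group(0)[0], m.start() + 1, m.end()) for m in re.finditer(r"(.)\1*", string)]

    segments: list[Segment] = []
    for idx, (ch, start, end) in enumerate(runs):
        kind = _CHAR_TO_KIND[ch]
        prev_ch = runs[idx - 1][0] if idx > 0 else None
        next_ch = runs[idx + 1][0] if idx + 1 < len(runs) else None
        if kind in LOOP_KINDS:
            segments.append(Segment(kind, start, end))
        elif kind is SegmentKind.SIGNAL_PEPTIDE:
            if idx != 0:
                raise TopologyInconsistencyError(
                    f"signal peptide run at {start}-{end} is not N-terminal"
                )
            segments.append(Segment(kind, start, end))
        else:
            if prev_ch not in ("i", "o") or next_ch not in ("i", "o"):
                raise TopologyInconsistencyError(
                    f"{kind.value} at {start}-{end} not flanked by loops on both sides"
                )
            length = end - start + 1
            if length < MIN_HELIX_LEN:
                raise TopologyInconsistencyError(
                    f"{kind.value} at {start}-{end} shorter than {MIN_HELIX_LEN} residues"
                )
            if kind in CROSSING_KINDS:
                if prev_ch == next_ch:
                    raise TopologyInconsistencyError(
                        f"{kind.value} at {start}-{end} flanked by side "
                        f"'{prev_ch}' on both sides"
                    )
                if kind is SegmentKind.TM_HELIX and length < TYPICAL_TM_LEN:
                    warnings.warn(
                        f"TM helix at {start}-{end} is only {length} residues",
                        ShortTMHelixWarning,
                        stacklevel=2,
                    )
                orientation = "in_to_out" if prev_ch == "i" else "out_to_in"
                segments.append(Segment(kind, start, end, orientation=orientation))
            else:  # reentrant
                if prev_ch != next_ch:
                    raise TopologyInconsistencyError(
                        f"reentrant helix at {start}-{end} flanked by different "
                        f"sides '{prev_ch}'/'{next_ch}'"
                    )
                rside = "in_in" if prev_ch == "i" else "out_out"
                segments.append(Segment(kind, start, end, reentrant_side=rside))
    return Topology(chain_length=len(string), segments=segments, source=source)


# ---------------------------------------------------------------------------
# topology-label algebra
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^(\d+)H(?:-(\d+)(BH|RH))?-N(in|out)$")


@dataclass(frozen=True)
class TopologyLabel:
    """Compact family label, e.g. ``10H-2BH-Nin`` or ``3H-Nout``."""

    n_canonical: int
    n_noncanonical: int = 0
    noncanonical_kind: str = "none"  # BH | RH | none
    n_term_side: str = "Nin"  # Nin | Nout

    def __post_init__(self) -> None:
        if self.n_canonical < 0 or self.n_noncanonical < 0:
            raise TopologyError("negative helix count")
        if self.n_noncanonical > 0 and self.noncanonical_kind not in ("BH", "RH"):
            raise TopologyError("non-canonical helices present but kind unset")
        if self.n_noncanonical == 0 and self.noncanonical_kind != "none":
            raise TopologyError("non-canonical kind set but count is zero")
        if self.n_term_side not in ("Nin", "Nout"):
            raise TopologyError(f"bad N-terminal side {self.n_term_side!r}")

    def __str__(self) -> str:
        mid = (
            f"-{self.n_noncanonical}{self.noncanonical_kind}"
            if self.n_noncanonical
            else ""
        )
        return f"{self.n_canonical}H{mid}-{self.n_term_side}"

    serialize = __str__

    @classmethod
    def parse(cls, text: str) -> "TopologyLabel":
        m = _LABEL_RE.match(text.strip())
        if not m:
            raise TopologyError(f"unparseable topology label {text!r}")
        n, m_count, kind, side = m.groups()
        return cls(
            n_canonical=int(n),
            n_noncanonical=int(m_count) if m_count else 0,
            noncanonical_kind=kind if kind else "none",
            n_term_side=f"N{side}",
        )


def topology_label(t: Topology) -> TopologyLabel:
    """Label a topology: all helices counted, orientation from the N-terminus.

    Broken and reentrant helices in one chain are rejected: no known
    transporter family mixes the two non-canonical kinds.
    """
    n_tm = sum(1 for s in t.helices() if s.kind is SegmentKind.TM_HELIX)
    n_b = sum(1 for s in t.helices() if s.kind is SegmentKind.BROKEN_HELIX)
    n_r = sum(1 for s in t.helices() if s.kind is SegmentKind.REENTRANT_HELIX)
    if n_b and n_r:
        raise UnsupportedMixtureError(
            f"chain mixes {n_b} broken and {n_r} reentrant helices"
        )
    if n_tm + n_b + n_r == 0:
        raise TopologyError("topology has no helices to label")
    kind = "BH" if n_b else ("RH" if n_r else "none")
    return TopologyLabel(
        n_canonical=n_tm,
        n_noncanonical=n_b + n_r,
        noncanonical_kind=kind,
        n_term_side=t.n_term_side,
    )


def total_helix_count(label: TopologyLabel) -> int:
    """Canonical plus non-canonical helices, counted together."""
    return label.n_canonical + label.n_noncanonical


def membrane_crossing_count(t: Topology) -> int:
    """Number of membrane crossings: TM + broken; reentrant helices do not cross."""
    return sum(1 for s in t.helices() if s.kind in CROSSING_KINDS)


# ---------------------------------------------------------------------------
# repeats and subdomains
# ---------------------------------------------------------------------------


@dataclass
class RepeatAnnotation:
    """Inverted-repeat decomposition plus per-helix subdomain tags.

    ``helix_tags[k]`` tags the k-th helix (chain order, signal peptides
    excluded) as 'scaffold' or 'core'. ``extrapolated`` and ``shuffled``
    are set by annotation transfer, not by construction.
    """

    n_repeat: tuple[int, int]
    c_repeat: tuple[int, int]
    helix_tags: list[str] = field(default_factory=list)
    extrapolated: set[int] = field(default_factory=set)
    shuffled: bool = False

    def __post_init__(self) -> None:
        (ns, ne), (cs, ce) = self.n_repeat, self.c_repeat
        if not (ns <= ne < cs <= ce):
            raise TopologyError(
                f"repeats must be disjoint and N before C, got {self.n_repeat} "
                f"and {self.c_repeat}"
            )
        for tag in self.helix_tags:
            if tag not in ("scaffold", "core"):
                raise TopologyError(f"bad subdomain tag {tag!r}")

    def repeat_of(self, segment: Segment) -> Optional[str]:
        """'N', 'C' or None (linker/tail) by midpoint membership."""
        mid = (segment.start + segment.end) // 2
        if self.n_repeat[0] <= mid <= self.n_repeat[1]:
            return "N"
        if self.c_repeat[0] <= mid <= self.c_repeat[1]:
            return "C"
        return None

    def helix_repeat_roles(self, t: Topology) -> list[Optional[str]]:
        return [self.repeat_of(h) for h in t.helices()]


def split_repeats(t: Topology, ann: RepeatAnnotation) -> tuple[Topology, Topology]:
    """Cut a topology into its N- and C-terminal repeat units.

    Repeat boundaries must fall inside loop segments; both returned
    sub-topologies keep absolute residue coordinates.
    """
    for bound in (*ann.n_repeat, *ann.c_repeat):
        seg = t.segment_at(bound)
        if seg.kind not in LOOP_KINDS:
            raise RepeatBoundaryError(
                f"repeat boundary {bound} falls inside {seg.kind.value} "
                f"{seg.start}-{seg.end}"
            )
    return _slice(t, *ann.n_repeat), _slice(t, *ann.c_repeat)


def _slice(t: Topology, start: int, end: int) -> Topology:
    kept: list[Segment] = []
    for seg in t.segments:
        if seg.end < start or seg.start > end:
            continue
        s, e = max(seg.start, start), min(seg.end, end)
        if (s, e) != (seg.start, seg.end):
            if seg.kind not in LOOP_KINDS:
                raise RepeatBoundaryError(
                    f"slice {start}-{end} cuts {seg.kind.value} {seg.start}-{seg.end}"
                )
            seg = replace(seg, start=s, end=e)
        kept.append(seg)
    return Topology(
        chain_length=end - start + 1,
        segments=kept,
        source=t.source,
        first_residue=start,
    )


# ---------------------------------------------------------------------------
# side re-propagation (shared by consensus repair and missing-helix insertion)
# ---------------------------------------------------------------------------


def propagate_sides(skeleton: str, n_term_side: str) -> str:
    """Rewrite the loop sides of a per-residue skeleton from the N-terminus.

    ``skeleton`` uses 'L' (or i/o, ignored) for loop positions and M/B/R/S
    for helix/signal positions. TM and broken helices flip the side,
    reentrant helices and signal peptides do not. Returns a valid
    per-residue topology string anchored at ``n_term_side`` ('Nin'/'Nout').
    """
    side = "i" if n_term_side == "Nin" else "o"
    out: list[str] = []
    for ch, group in _runs(skeleton):
        if ch in ("L", "i", "o"):
            out.append(side * len(group))
        elif ch in ("M", "B"):
            out.append(ch * len(group))
            side = "o" if side == "i" else "i"
        elif ch in ("R", "S"):
            out.append(ch * len(group))
        else:
            raise TopologyError(f"bad skeleton character {ch!r}")
    return "".join(out)


def _runs(s: str) -> Iterable[tuple[str, str]]:
    for m in re.finditer(r"(.)\1*", s):
        yield m.group(0)[0], m.group(0)
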