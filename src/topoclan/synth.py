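"""Ground-truth generator for membrane-transporter families.

Families are simulated with the statistical structure the annotation
pipeline assumes: a repeat-structured topology blueprint (scaffold TM
helices around a core whose middle helix is broken or reentrant),
inside loops enriched in K/R at a tunable positive-inside strength,
Gly/Pro-enriched low-hydrophobicity non-canonical cores, divergence
along a known tree with loop-only indels (so the true alignment is known
by construction), and "predicted" topologies that corrupt the truth with
a TOPCONS-style error model (missed non-canonical helices, merged TM
pairs, flipped orientation).

All randomness is drawn from an explicitly threaded numpy Generator;
a fixed seed reproduces every output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .evo import MultipleTopologyAlignment, project_topology
from .network import FamilyHitRecord
from .topology import (
    RepeatAnnotation,
    Topology,
    parse_topology_string,
    propagate_sides,
)

# residue classes; substitutions stay within a class so that the
# hydrophobicity and charge signals decay slowly
HYDROPHOBIC = "AVILMFWC"
POLAR = "STNQGPYH"
POSITIVE = "KR"
NEGATIVE = "DE"
CLASSES = (HYDROPHOBIC, POLAR, POSITIVE, NEGATIVE)

TM_POOL = "LLLIIVVFAFMW"  # strongly hydrophobic
# K/R-free: all loop K/R enters through positive_inside_strength, so that
# strength 0 means exactly no positive-inside signal (the bias statistic is
# a raw count difference and inside/outside window areas need not balance)
LOOP_POOL = "GGSSTTNNQQPDEAHLV"
CORE_FILL_POOL = "ASTGVNQLI"  # moderate hydrophobicity for non-canonical cores
BREAK_POOL = "GSTND"  # the mid-membrane discontinuity of a broken helix

#: baseline per-site K/R probability of the loop pool (both sides)
LOOP_KR_BASELINE = sum(1 for c in LOOP_POOL if c in "KR") / len(LOOP_POOL)


class SpecError(ValueError):
    pass


@dataclass
class PredictionErrorModel:
    p_miss_noncanonical: float = 0.0  # per non-canonical helix per sequence
    p_merge: float = 0.0  # per mergeable TM pair per sequence
    p_flip_orientation: float = 0.0  # per sequence

    def __post_init__(self) -> None:
        for v in (self.p_miss_noncanonical, self.p_merge, self.p_flip_orientation):
            if not 0 <= v <= 1:
                raise SpecError("error probabilities must be in [0, 1]")


def make_blueprint(
    n_tm: int,
    noncanonical: str = "none",  # BH | RH | none
    n_term: str = "Nin",
    tm_len: int = 21,
    reentrant_len: int = 12,
    broken_len: int = 21,
    loop_len: int = 15,
    tail_len: int = 20,
) -> tuple[Topology, Optional[RepeatAnnotation]]:
    """Repeat-structured topology blueprint.

    With a non-canonical kind the chain is two inverted repeat units,
    each "scaffold TMs + (core TM, non-canonical helix, core TM)"; the
    TM count is split N-repeat floor / C-repeat ceil. Without one, the
    chain is a plain n_tm-helix bundle and carries no repeat annotation.
    """
    if noncanonical not in ("BH", "RH", "none"):
        raise SpecError(f"bad noncanonical kind {noncanonical!r}")
    if noncanonical == "none":
        units = ["M"] * n_tm
        tags: list[str] = []
    else:
        if n_tm < 4:
            raise SpecError("need at least 4 TM helices for a two-repeat core")
        nc_char = "B" if noncanonical == "BH" else "R"
        n_half, c_half = n_tm // 2, n_tm - n_tm // 2
        units, tags = [], []
        for half in (n_half, c_half):
            units += ["M"] * (half - 2) + ["M", nc_char, "M"]
            tags += ["scaffold"] * (half - 2) + ["core", "core", "core"]
    lengths = {
        "M": tm_len,
        "B": broken_len,
        "R": reentrant_len,
    }
    skeleton = "L" * tail_len
    for u in units:
        skeleton += lengths[u] * u + "L" * loop_len
    skeleton = skeleton[: -loop_len] + "L" * tail_len
    string = propagate_sides(skeleton, n_term)
    topo = parse_topology_string(string, source="template")
    if noncanonical == "none":
        return topo, None
    helices = topo.helices()
    n_units = len(units) // 2
    cut = (helices[n_units - 1].end + helices[n_units].start) // 2
    ann = RepeatAnnotation(
        n_repeat=(1, cut),
        c_repeat=(cut + 1, topo.chain_length),
        helix_tags=tags,
    )
    return topo, ann


@dataclass
class FamilySpec:
    blueprint: Topology
    annotation: Optional[RepeatAnnotation] = None
    n_sequences: int = 20
    tree_shape: str = "balanced"  # balanced | caterpillar | star
    substitution_rate: float = 0.05  # per site per branch
    indel_rate: float = 0.0  # per loop segment per branch (loops only)
    positive_inside_strength: float = 2.0  # expected excess K/R per inside loop
    core_gly_pro_enrichment: float = 0.5
    error_model: PredictionErrorModel = field(default_factory=PredictionErrorModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.substitution_rate, self.indel_rate, self.core_gly_pro_enrichment):
            if not 0 <= v <= 1:
                raise SpecError("rates must be in [0, 1]")
        if self.positive_inside_strength < 0:
            raise SpecError("positive_inside_strength must be non-negative")
        if self.n_sequences < 1:
            raise SpecError("need at least one sequence")
        if self.tree_shape not in ("balanced", "caterpillar", "star"):
            raise SpecError(f"unknown tree shape {self.tree_shape!r}")


@dataclass
class SyntheticFamily:
    msa: dict[str, str]  # id -> gapped sequence
    true_strings: dict[str, str]  # id -> per-residue topology (degapped)
    predicted_strings: dict[str, str]
    tree_newick: str
    annotation: Optional[RepeatAnnotation]
    blueprint: Topology

    def true_topology(self, rid: str) -> Topology:
        return parse_topology_string(self.true_strings[rid])

    def mta(self, predicted: bool = True) -> MultipleTopologyAlignment:
        import dendropy

        src = self.predicted_strings if predicted else self.true_strings
        rows = {
            rid: project_topology(self.msa[rid], parse_topology_string(src[rid]))
            for rid in self.msa
        }
        tree = dendropy.Tree.get(
            data=self.tree_newick, schema="newick", preserve_underscores=True
        )
        return MultipleTopologyAlignment(rows=rows, tree=tree)


# ---------------------------------------------------------------------------
# sequence evolution machinery
# ---------------------------------------------------------------------------


class _Evolver:
    """Evolves (residue, state) columns along a tree with a known alignment.

    A global ordered list of column ids accommodates every lineage's
    insertions, so the true MSA falls out by construction.
    """

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.columns: list[int] = []
        self._next_col = 0
        # stationary inside-loop K/R enrichment (set from the blueprint):
        # probability of forcing a K/R at an inside-loop site so that the
        # expected per-site K/R probability is baseline + delta
        self.p_force_kr = 0.0

    def _draw_loop_residue(self, state: str) -> str:
        rng = self.rng
        if state == "i" and rng.random() < self.p_force_kr:
            return "K" if rng.random() < 0.5 else "R"
        return LOOP_POOL[rng.integers(len(LOOP_POOL))]

    def new_column(self, after: Optional[int]) -> int:
        cid = self._next_col
        self._next_col += 1
        if after is None:
            self.columns.insert(0, cid)
        else:
            self.columns.insert(self.columns.index(after) + 1, cid)
        return cid

    def root_from_blueprint(
        self,
        blueprint: Topology,
        positive_inside_strength: float,
        core_gly_pro_enrichment: float,
    ) -> dict[int, tuple[str, str]]:
        states = blueprint.to_string()
        node: dict[int, tuple[str, str]] = {}
        cols = []
        for _ in states:
            cid = self._next_col
            self._next_col += 1
            cols.append(cid)
        self.columns = list(cols)
        rng = self.rng
        # expected excess K/R per inside loop -> per-site forcing probability
        inside_lens = [
            seg.length
            for seg in blueprint.segments
            if states[seg.start - 1] == "i"
        ]
        if inside_lens and positive_inside_strength > 0:
            delta = positive_inside_strength / (sum(inside_lens) / len(inside_lens))
            self.p_force_kr = min(1.0, delta / (1.0 - LOOP_KR_BASELINE))
        for seg in blueprint.segments:
            for pos in range(seg.start, seg.end + 1):
                st = states[pos - 1]
                if st == "M":
                    res = TM_POOL[rng.integers(len(TM_POOL))]
                elif st in "BR":
                    broken_break = (
                        st == "B"
                        and seg.break_pos is not None
                        and abs(pos - seg.break_pos) <= 1
                    )
                    mid_break = (
                        st == "B"
                        and seg.break_pos is None
                        and abs(pos - (seg.start + seg.end) // 2) <= 1
                    )
                    if broken_break or mid_break:
                        res = BREAK_POOL[rng.integers(len(BREAK_POOL))]
                    elif rng.random() < core_gly_pro_enrichment:
                        res = "G" if rng.random() < 0.75 else "P"
                    else:
                        res = CORE_FILL_POOL[rng.integers(len(CORE_FILL_POOL))]
                else:  # loops and signal peptides
                    res = self._draw_loop_residue(st)
                node[cols[pos - 1]] = (res, st)
        return node

    def mutate(
        self,
        node: dict[int, tuple[str, str]],
        substitution_rate: float,
        indel_rate: float,
    ) -> dict[int, tuple[str, str]]:
        rng = self.rng
        child = dict(node)
        for cid, (res, st) in list(child.items()):
            if rng.random() < substitution_rate:
                if st in "ioS":
                    # loops resample from the side-aware stationary pool, so
                    # the positive-inside signal is refreshed, not inherited
                    child[cid] = (self._draw_loop_residue(st), st)
                else:
                    pool = next((c for c in CLASSES if res in c), POLAR)
                    child[cid] = (pool[rng.integers(len(pool))], st)
        if indel_rate > 0:
            self._apply_indels(child, indel_rate)
        return child

    def _apply_indels(self, node: dict[int, tuple[str, str]], indel_rate: float) -> None:
        rng = self.rng
        present = [c for c in self.columns if c in node]
        # loop runs in this lineage's current chain
        runs: list[list[int]] = []
        prev_state = ""
        for cid in present:
            st = node[cid][1]
            if st in "io":
                if runs and prev_state == st:
                    runs[-1].append(cid)
                else:
                    runs.append([cid])
            prev_state = st
        for run in runs:
            if rng.random() >= indel_rate:
                continue
            length = 1 + rng.geometric(0.5)
            if rng.random() < 0.5 and len(run) - length >= 5:  # deletion
                start = rng.integers(0, len(run) - length + 1)
                for cid in run[start : start + length]:
                    del node[cid]
            else:  # insertion
                anchor = run[rng.integers(len(run))]
                st = node[anchor][1]
                for _ in range(length):
                    cid = self.new_column(after=anchor)
                    node[cid] = (self._draw_loop_residue(st), st)
                    anchor = cid


def _tree_splits(n: int, shape: str) -> object:
    """Nested-list tree over leaf indices 0..n-1."""
    leaves = list(range(n))
    if n == 1:
        return leaves[0]
    if shape == "star":
        return leaves
    if shape == "caterpillar":
        node: object = leaves[0]
        for leaf in leaves[1:]:
            node = [node, leaf]
        return node

    def split(chunk: list[int]) -> object:
        if len(chunk) == 1:
            return chunk[0]
        mid = len(chunk) // 2
        return [split(chunk[:mid]), split(chunk[mid:])]

    return split(leaves)


def _newick(node: object, names: Sequence[str]) -> str:
    if isinstance(node, int):
        return f"{names[node]}:1.0"
    return "(" + ",".join(_newick(ch, names) for ch in node) + "):1.0"


def _evolve_tree(
    evolver: _Evolver,
    node: object,
    seq: dict[int, tuple[str, str]],
    spec: FamilySpec,
    out: dict[int, dict[int, tuple[str, str]]],
) -> None:
    if isinstance(node, int):
        out[node] = seq
        return
    for child in node:
        mutated = evolver.mutate(seq, spec.substitution_rate, spec.indel_rate)
        _evolve_tree(evolver, child, mutated, spec, out)


def _leaf_string(evolver: _Evolver, node: dict[int, tuple[str, str]], what: int) -> str:
    return "".join(
        node[c][what] if c in node else "-" for c in evolver.columns
    )


def corrupt_prediction(
    true_string: str, error_model: PredictionErrorModel, rng: np.random.Generator
) -> str:
    """Apply the TOPCONS-style error model to a true per-residue topology."""
    chars = list(true_string)
    runs = _runs_of(true_string)
    # missed non-canonical helices become loop
    for ch, s, e in runs:
        if ch in "BR" and rng.random() < error_model.p_miss_noncanonical:
            for k in range(s, e + 1):
                chars[k] = "L"
    # merged TM pairs: a loop strictly between two TM runs becomes helix
    for idx, (ch, s, e) in enumerate(runs):
        if (
            ch in "io"
            and 0 < idx < len(runs) - 1
            and runs[idx - 1][0] == "M"
            and runs[idx + 1][0] == "M"
            and rng.random() < error_model.p_merge
        ):
            for k in range(s, e + 1):
                chars[k] = "M"
    side = None
    for c in true_string:
        if c in "io":
            side = "Nin" if c == "i" else "Nout"
            break
    if side is None:
        side = "Nin"
    if rng.random() < error_model.p_flip_orientation:
        side = "Nout" if side == "Nin" else "Nin"
    skeleton = "".join("L" if c in "io" else c for c in chars)
    return propagate_sides(skeleton, side)


def corrupt_rows(
    rows: dict[str, str], rate: float, rng: np.random.Generator, alphabet: str = "ioMBRS"
) -> dict[str, str]:
    """Symmetric per-column channel noise on projected topology rows.

    Each non-gap character is, with probability ``rate``, replaced by a
    uniform draw from the other letters of the topology alphabet.
    """
    out = {}
    for rid, row in rows.items():
        chars = list(row)
        for k, c in enumerate(chars):
            if c != "-" and rng.random() < rate:
                choices = [a for a in alphabet if a != c]
                chars[k] = choices[rng.integers(len(choices))]
        out[rid] = "".join(chars)
    return out


def _runs_of(s: str) -> list[tuple[str, int, int]]:
    runs = []
    start = 0
    for i in range(1, len(s) + 1):
        if i == len(s) or s[i] != s[start]:
            runs.append((s[start], start, i - 1))
            start = i
    return runs


def generate_family(spec: FamilySpec) -> SyntheticFamily:
    """Simulate one family: true MSA, true and predicted topologies, tree."""
    if spec.blueprint.chain_length < 1:
        raise SpecError("empty blueprint")
    rng = np.random.default_rng(spec.seed)
    evolver = _Evolver(rng)
    root = evolver.root_from_blueprint(
        spec.blueprint, spec.positive_inside_strength, spec.core_gly_pro_enrichment
    )
    shape = _tree_splits(spec.n_sequences, spec.tree_shape)
    names = [f"seq{i:03d}" for i in range(spec.n_sequences)]
    leaves: dict[int, dict[int, tuple[str, str]]] = {}
    _evolve_tree(evolver, shape, root, spec, leaves)
    msa, truths, preds = {}, {}, {}
    for i, name in enumerate(names):
        node = leaves[i]
        msa[name] = _leaf_string(evolver, node, 0)
        truths[name] = _leaf_string(evolver, node, 1).replace("-", "")
        preds[name] = corrupt_prediction(truths[name], spec.error_model, rng)
    newick = _newick(shape, names).rsplit(":", 1)[0] + ";"
    return SyntheticFamily(
        msa=msa,
        true_strings=truths,
        predicted_strings=preds,
        tree_newick=newick,
        annotation=spec.annotation,
        blueprint=spec.blueprint,
    )


def generate_subfamily_mixture(
    spec_a: FamilySpec,
    spec_b_blueprint: Topology,
    shared_depth: int = 2,
    n_b: Optional[int] = None,
    error_model_b: Optional[PredictionErrorModel] = None,
) -> SyntheticFamily:
    """Two-clade family whose clades carry distinct topology labels.

    Clade A follows ``spec_a``. Clade B derives from the same root: the
    leading scaffold TM helices are deleted (or the non-canonical kind
    relabelled) until the blueprint of ``spec_b_blueprint`` is matched,
    and loop sides are re-anchored at clade B's own N-terminal side.
    ``shared_depth`` rounds of substitution separate the root from each
    clade ancestor.
    """
    rng = np.random.default_rng(spec_a.seed)
    evolver = _Evolver(rng)
    root = evolver.root_from_blueprint(
        spec_a.blueprint, spec_a.positive_inside_strength, spec_a.core_gly_pro_enrichment
    )
    anc_a = root
    for _ in range(shared_depth):
        anc_a = evolver.mutate(anc_a, spec_a.substitution_rate, 0.0)
    anc_b = root
    for _ in range(shared_depth):
        anc_b = evolver.mutate(anc_b, spec_a.substitution_rate, 0.0)
    anc_b = _retopologize(evolver, anc_b, spec_a.blueprint, spec_b_blueprint)

    n_b = n_b if n_b is not None else spec_a.n_sequences
    names_a = [f"A_seq{i:03d}" for i in range(spec_a.n_sequences)]
    names_b = [f"B_seq{i:03d}" for i in range(n_b)]
    shape_a = _tree_splits(spec_a.n_sequences, spec_a.tree_shape)
    shape_b = _tree_splits(n_b, spec_a.tree_shape)
    leaves_a: dict[int, dict[int, tuple[str, str]]] = {}
    leaves_b: dict[int, dict[int, tuple[str, str]]] = {}
    _evolve_tree(evolver, shape_a, anc_a, spec_a, leaves_a)
    _evolve_tree(evolver, shape_b, anc_b, spec_a, leaves_b)

    err_b = error_model_b or spec_a.error_model
    msa, truths, preds = {}, {}, {}
    for i, name in enumerate(names_a):
        msa[name] = _leaf_string(evolver, leaves_a[i], 0)
        truths[name] = _leaf_string(evolver, leaves_a[i], 1).replace("-", "")
        preds[name] = corrupt_prediction(truths[name], spec_a.error_model, rng)
    for i, name in enumerate(names_b):
        msa[name] = _leaf_string(evolver, leaves_b[i], 0)
        truths[name] = _leaf_string(evolver, leaves_b[i], 1).replace("-", "")
        preds[name] = corrupt_prediction(truths[name], err_b, rng)
    newick = (
        "("
        + _newick(shape_a, names_a)
        + ","
        + _newick(shape_b, names_b)
        + ");"
    )
    return SyntheticFamily(
        msa=msa,
        true_strings=truths,
        predicted_strings=preds,
        tree_newick=newick,
        annotation=spec_a.annotation,
        blueprint=spec_a.blueprint,
    )


def _retopologize(
    evolver: _Evolver,
    node: dict[int, tuple[str, str]],
    blueprint_a: Topology,
    blueprint_b: Topology,
) -> dict[int, tuple[str, str]]:
    """Edit a clade ancestor from blueprint A's topology to blueprint B's."""
    from .topology import topology_label

    lab_a, lab_b = topology_label(blueprint_a), topology_label(blueprint_b)
    out = dict(node)
    present = [c for c in evolver.columns if c in out]
    states = [out[c][1] for c in present]
    runs = _runs_of("".join(states))
    # delete leading scaffold TM helices to drop the canonical count
    d = lab_a.n_canonical - lab_b.n_canonical
    if d < 0:
        raise SpecError("mixture supports helix loss, not gain, in clade B")
    deleted = 0
    for ch, s, e in runs:
        if deleted >= d:
            break
        if ch == "M":
            for k in range(s, e + 1):
                del out[present[k]]
            deleted += 1
    # relabel non-canonical kind if the labels differ
    new_nc = {"BH": "B", "RH": "R"}.get(lab_b.noncanonical_kind)
    for cid, (res, st) in list(out.items()):
        if st in "BR" and new_nc is not None and st != new_nc:
            out[cid] = (res, new_nc)
    # re-anchor loop sides at clade B's own N-terminal side
    remaining = [c for c in evolver.columns if c in out]
    skeleton = "".join(
        "L" if out[c][1] in "io" else out[c][1] for c in remaining
    )
    repaired = propagate_sides(skeleton, lab_b.n_term_side)
    for c, st in zip(remaining, repaired):
        out[c] = (out[c][0], st)
    return out


# ---------------------------------------------------------------------------
# hit-table generator for network tests
# ---------------------------------------------------------------------------


@dataclass
class NetworkBlueprint:
    clusters: list[list[str]]
    satellites: dict[str, str] = field(default_factory=dict)  # satellite -> anchor
    outliers: list[str] = field(default_factory=list)
    bidirectional_fraction: float = 0.3

    def all_nodes(self) -> list[str]:
        nodes = [n for cl in self.clusters for n in cl]
        nodes += list(self.satellites)
        nodes += self.outliers
        return nodes


def generate_hit_table(
    blueprint: NetworkBlueprint, seed: int = 0
) -> list[FamilyHitRecord]:
    """Hits realizing a cluster/satellite/outlier structure.

    Within-cluster pairs draw E below 1e-3, satellite links in
    [1e-3, 0.1), outlier pairs at or above 0.1; a fraction of pairs is
    emitted in both directions with distinct E-values, exercising the
    bidirectional dedup rule.
    """
    rng = np.random.default_rng(seed)

    def log_uniform(lo_exp: float, hi_exp: float) -> float:
        return float(10 ** rng.uniform(lo_exp, hi_exp))

    hits: list[FamilyHitRecord] = []

    def emit(a: str, b: str, lo_exp: float, hi_exp: float) -> None:
        hits.append(FamilyHitRecord(a, b, log_uniform(lo_exp, hi_exp)))
        if rng.random() < blueprint.bidirectional_fraction:
            hits.append(FamilyHitRecord(b, a, log_uniform(lo_exp, hi_exp)))

    for cluster in blueprint.clusters:
        for i, a in enumerate(cluster):
            for b in cluster[i + 1 :]:
                emit(a, b, -40.0, -3.05)
    for satellite, anchor in blueprint.satellites.items():
        emit(satellite, anchor, -2.95, -1.01)
    anchors = [n for cl in blueprint.clusters for n in cl] or blueprint.outliers
    for outlier in blueprint.outliers:
        partner = anchors[int(rng.integers(len(anchors)))] if anchors else None
        if partner and partner != outlier:
            emit(outlier, partner, -0.9, 1.0)
    return hits
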