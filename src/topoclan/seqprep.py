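"""Family-set preprocessing: coverage/redundancy filtering, greedy identity
clustering and the effective-sequence-number (Meff) statistic.

Pairwise identity is defined as the number of identical aligned positions
divided by the shorter ungapped length. For unaligned sequence pairs the
aligned positions come from a basic global alignment with unit scores
(match 1, mismatch 0, gap 0); for MSA rows they come directly from the
alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str
    domain_span: tuple[int, int]  # 1-based inclusive span of the annotated domain

    def __post_init__(self) -> None:
        bad = set(self.residues.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: non-amino-acid characters {sorted(bad)}")
        s, e = self.domain_span
        if not (1 <= s <= e <= len(self.residues)):
            raise ValueError(f"{self.id}: domain_span {self.domain_span} outside sequence")


@dataclass
class FilterReport:
    kept: list[str] = field(default_factory=list)
    removed: dict[str, str] = field(default_factory=dict)  # id -> reason tag


@dataclass
class Cluster:
    centroid: str
    members: list[str]


def _unit_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner


_ALIGNER = _unit_aligner()


def pairwise_identity(a: str, b: str, aligned: bool = False) -> float:
    """Fraction of identical positions over the shorter ungapped length.

    With ``aligned=True`` the inputs are rows of one MSA (same length,
    '-' for gaps); otherwise they are raw sequences and a unit-score
    global alignment supplies the matched positions.
    """
    if aligned:
        if len(a) != len(b):
            raise ValueError("aligned rows differ in length")
        matches = sum(
            1 for x, y in zip(a, b) if x != "-" and y != "-" and x.upper() == y.upper()
        )
        shorter = min(len(a.replace("-", "")), len(b.replace("-", "")))
    else:
        a, b = a.upper(), b.upper()
        if not a or not b:
            return 0.0
        aln = _ALIGNER.align(a, b)[0]
        matches = 0
        for (qs, qe), (ts, te) in zip(*aln.aligned):
            matches += sum(1 for i, j in zip(range(qs, qe), range(ts, te)) if a[i] == b[j])
        shorter = min(len(a), len(b))
    if shorter == 0:
        return 0.0
    return matches / shorter


def filter_family(
    records: Sequence[SequenceRecord],
    domain_length: int,
    min_coverage: float = 0.75,
    max_identity: float = 0.90,
) -> FilterReport:
    """Drop fragments (<75% domain coverage) and near-duplicates (>90% identity).

    Coverage is the annotated domain span length over the reference domain
    length; records at exactly the coverage threshold are kept, records at
    exactly the identity threshold are kept (strict inequalities, matching
    the "<75%" / ">90%" rules). Of a too-similar pair, the later record in
    input order is removed.
    """
    if domain_length <= 0:
        raise ValueError("domain_length must be positive")
    report = FilterReport()
    survivors: list[SequenceRecord] = []
    for rec in records:
        s, e = rec.domain_span
        coverage = (e - s + 1) / domain_length
        if coverage < min_coverage:
            report.removed[rec.id] = "low_coverage"
        else:
            survivors.append(rec)
    kept_records: list[SequenceRecord] = []
    for rec in survivors:
        if any(
            pairwise_identity(rec.residues, prev.residues) > max_identity
            for prev in kept_records
        ):
            report.removed[rec.id] = "redundant"
        else:
            kept_records.append(rec)
            report.kept.append(rec.id)
    return report


def greedy_cluster(
    records: Sequence[tuple[str, str]],
    identity_threshold: float,
    aligned: bool = False,
) -> list[Cluster]:
    """Greedy centroid clustering at an identity threshold.

    ``records`` are (id, sequence) pairs. Candidates are scanned in
    descending ungapped length (ties broken by id) — the cd-hit convention.
    A candidate joins the first existing centroid it matches at
    ``identity >= identity_threshold``; otherwise it founds a new cluster.
    """
    if not 0 < identity_threshold < 1:
        raise ValueError("identity_threshold must be in (0, 1)")
    order = sorted(records, key=lambda r: (-len(r[1].replace("-", "")), r[0]))
    clusters: list[Cluster] = []
    seqs: dict[str, str] = dict(records)
    for rid, seq in order:
        for cl in clusters:
            if pairwise_identity(seq, seqs[cl.centroid], aligned=aligned) >= identity_threshold:
                cl.members.append(rid)
                break
        else:
            clusters.append(Cluster(centroid=rid, members=[rid]))
    return clusters


def compute_meff(
    msa: Sequence[tuple[str, str]] | dict[str, str],
    identity_threshold: float = 0.62,
) -> int:
    """Effective number of sequences: clusters at 62% ungapped identity.

    ``msa`` maps row ids to gapped rows of equal aligned length.
    """
    items = list(msa.items()) if isinstance(msa, dict) else list(msa)
    if not items:
        return 0
    lengths = {len(row) for _, row in items}
    if len(lengths) != 1:
        raise ValueError("MSA rows differ in aligned length")
    if len(items) == 1:
        return 1
    return len(greedy_cluster(items, identity_threshold, aligned=True))
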