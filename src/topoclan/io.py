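"""File formats.

- Aligned FASTA (Biopython) for MSAs.
- Topology files: FASTA-like pairs of records per entry — ``>id`` with
  the (possibly gapped) sequence, then ``>id|topology`` with the
  same-length per-residue topology string (TOPCONS dialect with the
  B/R/S extensions).
- Hit tables: TSV with columns query_id, template_id, e_value, identity,
  q_aln, t_aln (gapped alignment strings) and optional template_type.
- Trees: newick via dendropy.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .network import FamilyHitRecord
from .topology import RepeatAnnotation
from .transfer import PairwiseAlignment

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: PathLike, rows: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=rid, description="") for rid, s in rows.items()]
    SeqIO.write(records, str(path), "fasta")


def read_topology_file(path: PathLike) -> tuple[dict[str, str], dict[str, str]]:
    """Returns (sequences, topology strings), both possibly gapped."""
    seqs: dict[str, str] = {}
    topos: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id.endswith("|topology"):
            topos[rec.id[: -len("|topology")]] = str(rec.seq)
        else:
            seqs[rec.id] = str(rec.seq)
    missing = set(seqs) ^ set(topos)
    if missing:
        raise ValueError(f"unpaired records in topology file: {sorted(missing)}")
    for rid in seqs:
        if len(seqs[rid]) != len(topos[rid]):
            raise ValueError(f"{rid}: sequence and topology lengths differ")
    return seqs, topos


def write_topology_file(
    path: PathLike, seqs: dict[str, str], topos: dict[str, str]
) -> None:
    buf = _io.StringIO()
    for rid, seq in seqs.items():
        buf.write(f">{rid}\n{seq}\n>{rid}|topology\n{topos[rid]}\n")
    Path(path).write_text(buf.getvalue())


def read_tree(path: PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


HIT_COLUMNS = ["query_id", "template_id", "e_value", "identity", "q_aln", "t_aln"]


def read_hit_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "template_id": str})
    missing = set(HIT_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"hit table lacks columns {sorted(missing)}")
    return df


def hit_row_to_alignment(row: pd.Series) -> PairwiseAlignment:
    return PairwiseAlignment.from_gapped(
        str(row["query_id"]),
        str(row["template_id"]),
        str(row["q_aln"]),
        str(row["t_aln"]),
        float(row["e_value"]),
        float(row.get("identity", 0.0)),
        int(row.get("q_start", 1)),
        int(row.get("t_start", 1)),
    )


def read_family_hits(path: PathLike) -> list[FamilyHitRecord]:
    """Family-level hits for network building: query, hit, e_value[, span]."""
    df = pd.read_csv(path, sep="\t")
    hits = []
    for _, row in df.iterrows():
        span: Optional[tuple[int, int]] = None
        if "hit_start" in df.columns and not pd.isna(row["hit_start"]):
            span = (int(row["hit_start"]), int(row["hit_end"]))
        hits.append(FamilyHitRecord(str(row["query"]), str(row["hit"]), float(row["e_value"]), span))
    return hits


def write_family_hits(path: PathLike, hits: list[FamilyHitRecord]) -> None:
    rows = []
    for h in hits:
        rows.append(
            {
                "query": h.query,
                "hit": h.hit,
                "e_value": h.e_value,
                "hit_start": h.hit_span[0] if h.hit_span else "",
                "hit_end": h.hit_span[1] if h.hit_span else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_repeat_annotation(path: PathLike) -> RepeatAnnotation:
    """Repeat/subdomain TSV: first two rows give repeat spans, rest helix tags.

    Format::

        repeat	start	end
        N	1	240
        C	241	480
        helix	0	scaffold
        helix	1	core
        ...
    """
    n_span = c_span = None
    tags: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.strip().split("\t")
        if not parts or parts[0] in ("", "repeat"):
            continue
        if parts[0] == "N":
            n_span = (int(parts[1]), int(parts[2]))
        elif parts[0] == "C":
            c_span = (int(parts[1]), int(parts[2]))
        elif parts[0] == "helix":
            tags[int(parts[1])] = parts[2]
    if n_span is None or c_span is None:
        raise ValueError("repeat annotation lacks N/C spans")
    helix_tags = [tags[k] for k in sorted(tags)]
    return RepeatAnnotation(n_repeat=n_span, c_repeat=c_span, helix_tags=helix_tags)


def write_repeat_annotation(path: PathLike, ann: RepeatAnnotation) -> None:
    lines = ["repeat\tstart\tend"]
    lines.append(f"N\t{ann.n_repeat[0]}\t{ann.n_repeat[1]}")
    lines.append(f"C\t{ann.c_repeat[0]}\t{ann.c_repeat[1]}")
    for k, tag in enumerate(ann.helix_tags):
        flag = "\textrapolated" if k in ann.extrapolated else ""
        lines.append(f"helix\t{k}\t{tag}{flag}")
    if ann.shuffled:
        lines.append("shuffled\ttrue")
    Path(path).write_text("\n".join(lines) + "\n")
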