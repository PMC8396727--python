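"""Core-helix sequence features: position-frequency motifs with information
content, and an additive insertion free-energy (dG) score.

The dG score sums position-independent per-residue contributions from the
biological (translocon) hydrophobicity scale shipped with the package; it
is meant for comparative use (broken vs reentrant vs TM helices), not to
reproduce any particular server's absolute values.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .topology import RepeatAnnotation, Segment, SegmentKind, Topology

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MAX_IC = math.log2(20)


def _load_scale() -> dict[str, float]:
    with resources.files("topoclan.data").joinpath("dg_scale.json").open() as fh:
        return json.load(fh)["coefficients"]


DG_SCALE: dict[str, float] = _load_scale()


@dataclass
class MotifMatrix:
    """Per-column amino-acid frequencies plus information content (bits)."""

    frequencies: pd.DataFrame  # rows: positions, columns: 20 amino acids
    information: np.ndarray  # bits per column
    n_sequences: int

    def __post_init__(self) -> None:
        sums = self.frequencies.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("column frequencies must sum to 1")
        if ((self.information < -1e-12) | (self.information > MAX_IC + 1e-12)).any():
            raise ValueError("information content outside [0, log2 20]")


def extract_core_helix_submsa(
    msa: Mapping[str, str],
    representative_id: str,
    topology: Topology,
    annotation: RepeatAnnotation,
    repeat: str,
) -> dict[str, str]:
    """Columns of the family MSA spanned by one repeat's non-canonical core helix.

    ``repeat`` is 'N' or 'C'. The helix is located on the representative
    sequence; all rows are returned over exactly those columns (gap-only
    columns included).
    """
    helix = _noncanonical_core_helix(topology, annotation, repeat)
    rep_row = msa[representative_id]
    cols = _residue_columns(rep_row, helix.start, helix.end, topology.first_residue)
    return {rid: "".join(row[c] for c in cols) for rid, row in msa.items()}


def _noncanonical_core_helix(
    topology: Topology, annotation: RepeatAnnotation, repeat: str
) -> Segment:
    helices = topology.helices()
    roles = annotation.helix_repeat_roles(topology)
    candidates = [
        h
        for h, tag, role in zip(helices, annotation.helix_tags, roles)
        if tag == "core"
        and role == repeat
        and h.kind in (SegmentKind.BROKEN_HELIX, SegmentKind.REENTRANT_HELIX)
    ]
    if not candidates:
        raise ValueError(f"no broken/reentrant core helix in the {repeat}-repeat")
    return candidates[0]


def _residue_columns(rep_row: str, start: int, end: int, first_residue: int) -> list[int]:
    cols = []
    res = first_residue - 1
    for col, ch in enumerate(rep_row):
        if ch != "-":
            res += 1
            if start <= res <= end:
                cols.append(col)
    if not cols:
        raise ValueError(f"residues {start}-{end} not present in representative row")
    return cols


def motif(sub_msa: Mapping[str, str], pseudocount: float = 0.5 / 20) -> MotifMatrix:
    """Position-frequency matrix with per-column information content.

    ``pseudocount`` is added to every cell count; gaps and non-standard
    residues are ignored. IC = log2(20) - Shannon entropy of the column.
    """
    rows = list(sub_msa.values())
    if not rows:
        raise ValueError("empty sub-alignment")
    width = len(rows[0])
    freqs = np.full((width, 20), pseudocount, dtype=float)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for row in rows:
        for j, ch in enumerate(row.upper()):
            if ch in aa_index:
                freqs[j, aa_index[ch]] += 1.0
    totals = freqs.sum(axis=1, keepdims=True)
    # a column of only gaps with pseudocount 0 would be 0/0: call it uniform
    zero = totals[:, 0] == 0
    freqs[zero] = 1.0 / 20
    totals[zero] = 1.0
    probs = freqs / freqs.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = np.clip(MAX_IC - entropy, 0.0, MAX_IC)
    frame = pd.DataFrame(probs, columns=list(AMINO_ACIDS))
    return MotifMatrix(frequencies=frame, information=ic, n_sequences=len(rows))


def delta_g(helix_residues: str) -> float:
    """Additive insertion free energy of a helix, kcal/mol scale.

    Lower (more negative) means more favourable membrane insertion.
    Accepts helices of 9-40 residues; non-standard residues are skipped
    with a warning.
    """
    seq = helix_residues.upper().replace("-", "")
    if not seq:
        raise ValueError("empty helix")
    if not 9 <= len(seq) <= 40:
        raise ValueError(f"helix length {len(seq)} outside 9..40")
    total = 0.0
    for ch in seq:
        coeff = DG_SCALE.get(ch)
        if coeff is None:
            warnings.warn(f"skipping non-standard residue {ch!r}", stacklevel=2)
            continue
        total += coeff
    return total


def fold_type_feature_summary(
    families: Mapping[str, Sequence[str]],
    quantiles: Sequence[float] = (0.25, 0.5, 0.75),
) -> pd.DataFrame:
    """Distributions of core-helix dG and Gly/Pro frequency per fold-type group.

    ``families`` maps a group label (e.g. 'broken', 'reentrant') to the
    core-helix residue strings of its member families.
    """
    if len(families) < 2:
        raise ValueError("need at least two labelled groups")
    records = []
    for label, helices in families.items():
        dgs = [delta_g(h) for h in helices]
        gp = [
            sum(1 for c in h.upper() if c in "GP") / max(1, len(h.replace("-", "")))
            for h in helices
        ]
        row: dict[str, float | str] = {
            "group": label,
            "n": len(helices),
            "dg_mean": float(np.mean(dgs)),
            "gly_pro_mean": float(np.mean(gp)),
        }
        for q in quantiles:
            row[f"dg_q{int(q * 100)}"] = float(np.quantile(dgs, q))
            row[f"gly_pro_q{int(q * 100)}"] = float(np.quantile(gp, q))
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("group")
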