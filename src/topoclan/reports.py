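"""Dotplot and distance-map data products.

The canonical outputs are plain tables (point lists and matrices); PNG
rendering through matplotlib is optional sugar on top.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .topology import Topology
from .transfer import PairwiseAlignment


@dataclass
class AlignmentDotplot:
    """Aligned residue pairs of one sequence pair, binned by E-value magnitude.

    Each point is (q_pos, t_pos, log10_e_bin) where the bin is
    floor(log10 E) of the alignment the pair came from. Helix spans of
    both sequences are kept for axis annotation (TM vs reentrant).
    """

    points: list[tuple[int, int, int]] = field(default_factory=list)
    q_helix_spans: list[tuple[int, int, str]] = field(default_factory=list)
    t_helix_spans: list[tuple[int, int, str]] = field(default_factory=list)


def _helix_spans(t: Optional[Topology]) -> list[tuple[int, int, str]]:
    if t is None:
        return []
    return [(h.start, h.end, h.kind.value) for h in t.helices()]


def alignment_dotplot(
    alignments: Sequence[PairwiseAlignment],
    q_topology: Optional[Topology] = None,
    t_topology: Optional[Topology] = None,
) -> AlignmentDotplot:
    """Dotplot of one or more alternative alignments of the same pair."""
    pairs = {(a.query_id, a.template_id) for a in alignments}
    if len(pairs) > 1:
        raise ValueError(f"alignments mix sequence pairs: {sorted(pairs)}")
    plot = AlignmentDotplot(
        q_helix_spans=_helix_spans(q_topology),
        t_helix_spans=_helix_spans(t_topology),
    )
    for aln in alignments:
        e_bin = math.floor(math.log10(aln.e_value))
        for q, t in aln.aligned_pairs:
            plot.points.append((q, t, e_bin))
    return plot


@dataclass
class DistanceMap:
    """CA-CA distances in Angstrom; rendering clips to [clip_lo, clip_hi]."""

    matrix: np.ndarray
    clip_lo: float = 4.0
    clip_hi: float = 10.0

    def rendered(self) -> np.ndarray:
        return np.clip(self.matrix, self.clip_lo, self.clip_hi)


def read_ca_coordinates(pdb_path: str, chain_id: Optional[str] = None) -> np.ndarray:
    """CA coordinates from a PDB file: first model, first altloc, one chain."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", pdb_path)
    model = next(structure.get_models())
    coords = []
    for chain in model:
        if chain_id is not None and chain.id != chain_id:
            continue
        missing = 0
        for residue in chain:
            if "CA" in residue:
                coords.append(residue["CA"].get_coord())
            elif residue.id[0] == " ":
                missing += 1
        if missing:
            warnings.warn(f"chain {chain.id}: {missing} residues without CA skipped")
        break  # first matching chain only
    return np.asarray(coords, dtype=float)


def distance_map(
    coords_a: np.ndarray,
    coords_b: Optional[np.ndarray] = None,
    residue_map: Optional[Sequence[tuple[int, int]]] = None,
    mode: str = "cross",
    clip: tuple[float, float] = (4.0, 10.0),
) -> DistanceMap:
    """Inter-residue CA distance matrix.

    Without ``residue_map``: all-vs-all Euclidean distances between
    ``coords_a`` and ``coords_b`` (self-map when b is omitted). With a
    residue map of aligned (i, j) index pairs (0-based), ``mode='cross'``
    gives the distances between aligned residues and ``mode='difference'``
    the absolute difference of the two intra-chain distance matrices
    restricted to the aligned positions. Raw values are preserved;
    clipping applies at render time only.
    """
    from scipy.spatial.distance import cdist

    a = np.asarray(coords_a, dtype=float)
    b = a if coords_b is None else np.asarray(coords_b, dtype=float)
    if residue_map is None:
        return DistanceMap(cdist(a, b), *clip)
    idx_a = [i for i, _ in residue_map]
    idx_b = [j for _, j in residue_map]
    if max(idx_a, default=-1) >= len(a) or max(idx_b, default=-1) >= len(b):
        raise IndexError("residue_map indices outside coordinate arrays")
    if mode == "cross":
        return DistanceMap(cdist(a[idx_a], b[idx_b]), *clip)
    if mode == "difference":
        da = cdist(a[idx_a], a[idx_a])
        db = cdist(b[idx_b], b[idx_b])
        return DistanceMap(np.abs(da - db), *clip)
    raise ValueError(f"unknown mode {mode!r}")


def render_dotplot(plot: AlignmentDotplot, path: str) -> None:
    """Optional PNG/SVG rendering of a dotplot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if plot.points:
        qs, ts, bins = zip(*plot.points)
        sc = ax.scatter(qs, ts, c=bins, s=4, cmap="viridis")
        fig.colorbar(sc, label="floor(log10 E)")
    for start, end, kind in plot.q_helix_spans:
        color = "red" if kind == "reentrant_helix" else "blue"
        ax.axvspan(start, end, alpha=0.1, color=color)
    for start, end, kind in plot.t_helix_spans:
        color = "red" if kind == "reentrant_helix" else "blue"
        ax.axhspan(start, end, alpha=0.1, color=color)
    ax.set_xlabel("query position")
    ax.set_ylabel("template position")
    fig.savefig(path, dpi=150)
    plt.close(fig)
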