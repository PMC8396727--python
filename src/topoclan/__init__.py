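"""topoclan: evolution-guided topology annotation for membrane-transporter
families — consensus topologies from multiple topology alignments,
template-based broken/reentrant helix inference, positive-inside (KR-bias)
model selection, repeat/subdomain decomposition and E-value-weighted
family networks, with a ground-truth synthetic-family generator."""

from importlib import resources

import pandas as pd

from .topology import (
    RepeatAnnotation,
    Segment,
    SegmentKind,
    Topology,
    TopologyLabel,
    membrane_crossing_count,
    parse_topology_string,
    split_repeats,
    topology_label,
    total_helix_count,
)

__version__ = "0.1.0"

__all__ = [
    "RepeatAnnotation",
    "Segment",
    "SegmentKind",
    "Topology",
    "TopologyLabel",
    "membrane_crossing_count",
    "parse_topology_string",
    "split_repeats",
    "topology_label",
    "total_helix_count",
    "family_labels",
]


def family_labels() -> pd.DataFrame:
    """The packaged CPA/AT family table: family, fold_type, topology label."""
    with resources.files("topoclan.data").joinpath("family_labels.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
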