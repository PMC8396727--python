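"""End-to-end family annotation.

Chains the pipeline stages: predicted topologies are projected onto the
seed MSA and reordered by the tree; topology-consistent subfamilies are
split off; each subfamily's consensus "initial topology" is refined
against the best-scoring structural template (missing broken/reentrant
helices inserted, orientations re-propagated); subdomain and repeat
annotations are transferred; and the broken-vs-reentrant call is
validated by the positive-inside (KR-bias) rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import dendropy

from . import evo, krbias, transfer
from .topology import (
    RepeatAnnotation,
    SegmentKind,
    Topology,
    TopologyLabel,
    parse_topology_string,
    propagate_sides,
    topology_label,
)


class AnalysisConflictError(RuntimeError):
    """E-value-based and KR-bias-based type verdicts disagree."""

    def __init__(self, message: str, partial: "AnnotationResult"):
        super().__init__(message)
        self.partial = partial


@dataclass
class TemplateHit:
    """One structural-template hit for the representative sequence."""

    alignment: transfer.PairwiseAlignment
    template_type: str  # broken | reentrant
    template_topology: Topology
    template_annotation: Optional[RepeatAnnotation] = None


@dataclass
class AnnotationResult:
    group_label: TopologyLabel
    member_ids: list[str]
    representative: str
    initial: Topology
    final: Optional[Topology] = None
    final_label: Optional[TopologyLabel] = None
    annotation: Optional[RepeatAnnotation] = None
    kr_profile: Optional[krbias.KRBiasProfile] = None
    provenance: dict[str, Any] = field(default_factory=dict)


def alternative_model(final: Topology) -> Topology:
    """The competing topology model: broken and reentrant kinds swapped.

    Loop sides are re-propagated from the N-terminus, so the two models
    differ in every loop side downstream of the non-canonical helices.
    """
    swap = {"B": "R", "R": "B"}
    chars = [swap.get(c, c) for c in final.to_string()]
    skeleton = "".join("L" if c in "io" else c for c in chars)
    return parse_topology_string(
        propagate_sides(skeleton, final.n_term_side), source="final"
    )


def annotate_family(
    msa: dict[str, str],
    predicted: dict[str, str],
    tree: Optional[dendropy.Tree],
    template_hits: Sequence[TemplateHit],
    min_clade_fraction: float = 0.75,
    min_group_size: int = 3,
    kr_params: krbias.KRWindowParams = krbias.KRWindowParams(),
) -> list[AnnotationResult]:
    """Annotate every topology-consistent subfamily of one family.

    ``predicted`` maps row ids to degapped per-residue topology strings;
    ``template_hits`` align the (per-group) representative sequence to
    templates of known structure. Raises :class:`AnalysisConflictError`
    when the KR-bias verdict contradicts the E-value-chosen transporter
    type (the partial result rides on the exception).
    """
    rows = {
        rid: evo.project_topology(msa[rid], parse_topology_string(predicted[rid]))
        for rid in msa
    }
    mta = evo.MultipleTopologyAlignment(rows=rows, tree=tree)
    if tree is not None:
        mta = evo.reorder_by_tree(mta)
    else:
        warnings.warn("no tree given: subfamily split degrades to label equality")
    partition = evo.detect_topology_groups(mta, min_clade_fraction, min_group_size)

    results: list[AnnotationResult] = []
    for group in partition.groups:
        rep = evo.pick_representative(mta, group.member_ids)
        initial = evo.consensus_topology(mta, group.member_ids, representative=rep)
        result = AnnotationResult(
            group_label=group.label,
            member_ids=list(group.member_ids),
            representative=rep,
            initial=initial,
            provenance={
                "split": len(partition.groups) > 1,
                "n_groups": len(partition.groups),
                "deviants": list(partition.deviants),
                "degraded_no_tree": tree is None,
            },
        )
        if template_hits:
            _refine_with_templates(result, msa, group.member_ids, template_hits, kr_params)
        else:
            result.final = initial
            result.final_label = topology_label(initial)
            result.provenance["type_source"] = "none"
        results.append(result)
    return results


def _refine_with_templates(
    result: AnnotationResult,
    msa: dict[str, str],
    member_ids: Sequence[str],
    template_hits: Sequence[TemplateHit],
    kr_params: krbias.KRWindowParams,
) -> None:
    chosen_type: Optional[str] = None
    type_source = "evalue"
    try:
        chosen_type = transfer.choose_transporter_type(
            [(h.template_type, h.alignment.e_value) for h in template_hits]
        )
    except transfer.AmbiguousTypeError:
        type_source = "krbias"

    candidates = (
        [h for h in template_hits if h.template_type == chosen_type]
        if chosen_type
        else list(template_hits)
    )
    best = min(candidates, key=lambda h: h.alignment.e_value)
    records = transfer.classify_helices(
        best.alignment, result.initial, best.template_topology
    )
    final = transfer.infer_final_topology(
        result.initial, best.template_topology, records, best.alignment
    )
    result.final = final
    result.final_label = topology_label(final)
    result.provenance.update(
        {
            "template": best.alignment.template_id,
            "template_e_value": best.alignment.e_value,
            "missing_helices_added": sum(
                1 for r in records if r.cls in ("inside_loop", "outside_loop")
            ),
            "type_source": type_source,
        }
    )

    # KR-bias validation of the broken/reentrant call
    has_noncanonical = any(
        s.kind in (SegmentKind.BROKEN_HELIX, SegmentKind.REENTRANT_HELIX)
        for s in final.helices()
    )
    if has_noncanonical:
        alt = alternative_model(final)
        final_kind = result.final_label.noncanonical_kind
        model_broken = final if final_kind == "BH" else alt
        model_reentrant = final if final_kind == "RH" else alt
        sub_msa = {rid: msa[rid] for rid in member_ids}
        profile = krbias.select_topology_model(
            sub_msa, result.representative, model_broken, model_reentrant, kr_params
        )
        result.kr_profile = profile
        result.provenance["kr_verdict"] = profile.selected_model
        final_type = "broken" if final_kind == "BH" else "reentrant"
        if type_source == "krbias" and profile.selected_model != "ambiguous":
            # arbitration: the KR verdict decides the type
            if profile.selected_model != final_type:
                result.final = alt
                result.final_label = topology_label(alt)
            result.provenance["type_source"] = "krbias"
        elif (
            profile.selected_model != "ambiguous"
            and profile.selected_model != final_type
        ):
            raise AnalysisConflictError(
                f"E-value template type '{final_type}' contradicts KR-bias "
                f"verdict '{profile.selected_model}'",
                result,
            )

    # subdomain/repeat transfer when the template carries an annotation
    if best.template_annotation is not None:
        records_final = transfer.classify_helices(
            best.alignment, result.final, best.template_topology
        )
        try:
            result.annotation = transfer.transfer_subdomains(
                best.template_annotation,
                records_final,
                result.final,
                best.template_topology,
            )
        except transfer.TransferRefusedError as exc:
            result.provenance["subdomain_transfer"] = f"refused: {exc}"
        else:
            result.provenance["subdomain_transfer"] = "ok"
            if result.annotation.shuffled:
                result.provenance["repeat_shuffle"] = True
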